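"""Call primary hits from a simulated in vivo RNAi screen.

Hit lines block pupariation of the tumor-bearing larvae; a line is a hit
when its pupariation Z-score against the oncogene-only control exceeds
1.65, or when the tumor invades past the mouth hooks / seeds ectopic foci.
"""

from crosstum import SimConfig, call_primary_hits, filter_rnai_quality, gen_screen_table

cfg = SimConfig(seed=1, n_lines=2000, hit_fraction=0.05, pupariation_effect=35.0)
screen = gen_screen_table(cfg)

kept = filter_rnai_quality(screen.records)  # drop S19 < 0.8 or > 6 CAN repeats
calls = call_primary_hits(kept, screen.control, z_cutoff=1.65)

n_hits = int(calls["is_hit"].sum())
planted = screen.planted_hits[kept.index]
sens = calls.loc[planted.to_numpy(), "larval_arrest_hit"].mean()
print(f"lines screened: {len(screen.records)}, passed quality filter: {len(kept)}")
print(f"primary hits: {n_hits} ({int(calls['larval_arrest_hit'].sum())} larval arrest, "
      f"{int(calls['invasion_hit'].sum())} invasion)")
print(f"sensitivity vs planted truth: {sens:.2f}")
# The quality filter mirrors the published specificity rules; with a
# 35-point pupariation drop essentially every true modifier exceeds Z=1.65,
# while ~5% of null lines do (the normal tail beyond 1.65).
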