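"""Stability filtering and ranking on the published MetRS variant tables.

Uses the published folding and binding free-energy columns of the two
MetRS redesign studies as inputs: variants less stable than the reference
by more than the threshold are excluded from the affinity ranking, and the
rest are ranked by relative binding free energy.
"""

from landflat import rank_variants, top_report
from landflat.metrs import (
    ANL_FOLD_THRESHOLD,
    METAMP_FOLD_THRESHOLD,
    anl_variant_table,
    metamp_variant_table,
)

anl = rank_variants(anl_variant_table(), criterion="ddG_bind",
                    fold_threshold=ANL_FOLD_THRESHOLD)
excluded = list(anl.index[anl["filtered"]])
print(f"AnL study (reference SLL, filter at {ANL_FOLD_THRESHOLD} kcal/mol): "
      f"excluded {excluded} as insufficiently stable")

metamp = rank_variants(metamp_variant_table(), criterion="ddG_bind",
                       fold_threshold=METAMP_FOLD_THRESHOLD)
print(f"\nMetAMP study (reference LAI = wild type, filter at "
      f"{METAMP_FOLD_THRESHOLD} kcal/mol):")
print(top_report(metamp, n=6))
print(f"\nwild type LAI ranks {int(metamp.at['LAI', 'rank'])} of "
      f"{int(metamp['rank'].notna().sum())} ranked variants "
      "(rank 1 = tightest predicted binder)")
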