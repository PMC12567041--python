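"""Predictive-performance statistics over the transcribed verification
tables: fold errors for the PK summaries and the DDI/OI ratio studies."""
from ascipk.evaluation import (afe_aafe, gmfe, guest_limits, pk_table_pairs,
                               ratio_table_pairs)

for metric in ("cmax", "auc", "ctrough"):
    pairs = pk_table_pairs(metric)
    a, aa = afe_aafe(pairs)
    print(f"{metric:8s} n={len(pairs):2d}  AFE {a:.2f}  AAFE {aa:.2f}")
for metric in ("cmax", "auc"):
    pairs = ratio_table_pairs(metric)
    print(f"{metric} ratios: GMFE {gmfe(pairs):.2f} over {len(pairs)} studies")
print("Guest no-effect interval at R=1:", guest_limits(1.0))
# AFE near 1 means no systematic bias; AAFE <= 2 is the conventional
# success threshold for PBPK verification.
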