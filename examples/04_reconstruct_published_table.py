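"""Recover an exact 2×2 table from rounded published summary statistics.

Given class sizes (207 compression-positive and 641 negative limbs) and a
sensitivity/specificity printed to one decimal, enumerate all integer
tables consistent with the rounding. Here the inversion is unique, so the
predictive values and accuracy follow exactly.
"""

from vppg import reconstruct_table

res = reconstruct_table(n_pos=207, n_neg=641, sens_printed=60.9, spec_printed=47.6)
t = res.table  # raises if not unique
print(f"unique reconstruction: tp={t.tp} fn={t.fn} fp={t.fp} tn={t.tn}")
for name, value in t.metrics_pct().items():
    print(f"  {name:>22}: {value}%")

print(
    "\nPPV/NPV/accuracy are fully determined by the class sizes once the\n"
    "rounding windows pin down single tp and tn counts."
)

# an inconsistent report is detected rather than silently approximated
bad = reconstruct_table(10, 10, 55.0, 50.0)
print(f"\nn=10/10 with printed 55.0%/50.0%: consistent={bad.consistent}")
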