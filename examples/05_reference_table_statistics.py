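"""Regenerate the reference study's quoted summary statistics.

Loads the packaged transcription of the reference measurement tables
(noise metrics for two commercial reconstructions at three strength
levels and three dose levels) and recomputes the mean +/- SD
percent-difference statistics quoted in its results text.
"""

from ctiq import comparison as cmp

table = cmp.load_reference_tables()
print(table.to_string())
print()
for key, stat in cmp.reference_summary_statistics(table).items():
    print(f"{key:36s} {stat.mean:+6.1f} ± {stat.sd:4.1f}%")
print()
print("The NPS1D-peak contrast regenerates as -59.8 ± 7.3% — and only with")
print("the sample-SD (n-1) convention, which is how that convention was")
print("identified. The level-1-to-2 contrast of the super-resolution")
print("algorithm is rounding-limited: the rounded cells give -44.5 where")
print("the source text prints -44.4.")
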