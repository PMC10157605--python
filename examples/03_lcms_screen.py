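"""Classify chromatographic peaks of an LC-MS/MS run.

Simulates a run with one peptide eluting twice as resolved isomers, four
homogeneous peptides, and one peak hiding a co-eluting isomer pair.  The
screen sets the scan window to half the narrowest peak's scan count,
compares each peak's leading and trailing edges, derives the hypothesized
mean from single-peak edge means (upper quartile), and tests all same-
peptide peak pairs.
"""

from specdiff import simulate
from specdiff.lcms import peaks_from_table, screen

chrom = simulate.default_lc_scenario(seed=0)
series, peak_table = simulate.simulate_chromatogram(chrom, seed=1)
print(peak_table.drop(columns=["truth"]).to_string(index=False))

result = screen(series, peaks_from_table(peak_table), rule="upper_quartile")
print(f"\nscan window: {result.window} scans per extraction")
print(f"hypothesized mean ({result.mu0.rule}): {result.mu0.value:.5f}\n")
print(result.to_frame().to_string(index=False))

print(
    "\nP1's two peaks are confirmed isomers (centre windows differ), the"
    "\nfour homogeneous peptides are non-isomers (edges at the replicate"
    "\nfloor), and P6's significant edge difference exposes the co-eluting"
    "\nisomer hidden under its single apparent peak."
)
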