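"""Munge raw GWAS summary statistics into the canonical analysis form.

Builds a small raw association table with mixed column conventions,
restricts it to a SNP whitelist (the role a HapMap3 list plays),
excises the MHC region (chr6:25-34 Mb), derives z from beta/se, and
prints the filter accounting.
"""

import pandas as pd

import cellprior as cp

raw = pd.DataFrame(
    {
        "rsid": ["rs1", "rs2", "rs3", "rs4", "rs5", "rs6"],
        "CHR": ["1", "1", "6", "2", "2", "3"],
        "POS": [50_000, 80_000, 28_000_000, 10_000, 20_000, 5_000],
        "effect_allele": ["A", "C", "G", "A", "A", "C"],
        "other_allele": ["G", "T", "A", "G", "T", "G"],  # rs5 A/T, rs6 C/G
        "BETA": [0.02, -0.01, 0.05, 0.003, 0.01, 0.02],
        "SE": [0.01, 0.004, 0.01, 0.003, 0.01, 0.02],
        "P": [0.046, 0.012, 5e-7, 0.32, 0.32, 0.32],
        "N": [10_000] * 6,
    }
)
whitelist = {"rs1", "rs2", "rs3", "rs5", "rs6"}

stats, report = cp.munge(raw, whitelist)
print("canonical table:")
print(stats.to_string(index=False))
print("\nfilter report:")
print(report.to_json())
print("\nrs3 falls in the MHC, rs4 is off-whitelist, rs5/rs6 are "
      "strand-ambiguous; z = beta/se and chi2 = z^2 for the rest.")
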