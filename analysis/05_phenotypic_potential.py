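#!/usr/bin/env python
"""Score each strain's robustness by phenotypic potential (PP).

PP of a replicate is the fraction of the noise (cell-to-cell variability)
traits whose Z falls outside the reference strain's two-sided 95% envelope;
strains are compared to the control strain K7 by Dunnett's many-to-one test.
Writes results/pp.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from yeastmorph.catalog import read_catalog
from yeastmorph.robustness import dunnett_vs_control, pp_by_strain

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
parser.add_argument("--results", type=Path, default=Path("results"))
parser.add_argument("--control", default="K7")
args = parser.parse_args()

catalog = read_catalog(args.cohort / "catalog.tsv")
rep_z = pd.read_csv(args.results / "z_replicate.tsv",
                    sep="\t").set_index(["strain", "replicate"])
pps = pp_by_strain(rep_z, catalog)
results = dunnett_vs_control(pps, control=args.control, alpha=0.05)

df = pd.DataFrame([
    {"strain": r.strain_id, "pp_mean": r.mean, "pp_sd": r.sd,
     "adjusted_p": r.adjusted_p, "flagged": r.flagged_vs_control}
    for r in results
]).sort_values("pp_mean")
df.to_csv(args.results / "pp.tsv", sep="\t", index=False)

print(f"phenotypic potential ({catalog.n_noise_traits} noise traits, "
      f"Dunnett vs {args.control}):")
for _, row in df.iterrows():
    mark = " *" if row["flagged"] and row["pp_mean"] > df.loc[
        df['strain'] == args.control, 'pp_mean'].iloc[0] else ""
    print(f"  {row['strain']:<10} PP = {row['pp_mean']:.3f} "
          f"+/- {row['pp_sd']:.3f}{mark}")
print("  (* = significantly noisier than the control at adjusted P < 0.05)")
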