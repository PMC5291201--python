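"""Conditional analysis at loci with a known single-variant mQTL.

Regions 2 and 3 of the cohort carry a common index SNP: region 2 also has
an independent rare-variant effect, region 3's rare variants merely tag the
index haplotype.  Each region's rare set is pruned of variants in high LD
with the index (D' >= 0.8) and re-tested with the index SNP as a covariate.
The probe-overlap check (region 4) conditions on a rare variant lying in
the probe sequence itself.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from mqtlcollapse.conditional import (
    conditional_skat,
    estimate_dprime,
    probe_overlap_conditioning,
    prune_by_dprime,
)
from mqtlcollapse.simulate import default_study_config, simulate_dataset
from mqtlcollapse.skat import skat_test

OUT = Path("results/conditional")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ds = simulate_dataset(default_study_config(seed=0))
    v = ds.variants
    X = ds.covariates.to_numpy(float)
    rows = []
    for k, label in ((2, "index + independent rare set"), (3, "tagging only")):
        sel = v[(v["region"] == k) & (v["block"] >= 0)]
        G = ds.dosages[:, sel.index]
        idx_col = int(v.index[(v["region"] == k) & (v["id"].str.startswith("idx"))][0])
        idx = ds.dosages[:, idx_col]
        y = ds.methylation.loc[f"cg{k:08d}"].to_numpy(float)
        dprimes = [
            estimate_dprime(G[:, j], idx).D_prime for j in range(G.shape[1])
        ]
        retained = prune_by_dprime(G, sel["id"].tolist(), idx)
        row = {
            "region": k,
            "scenario": label,
            "n_variants": G.shape[1],
            "max_dprime_to_index": max(dprimes),
            "n_retained": len(retained),
            "p_unconditional": skat_test(y, X, G, mafs=sel["maf"].to_numpy()).p_value,
        }
        if len(retained) >= 2:
            keep = [sel["id"].tolist().index(x) for x in retained]
            row["p_conditional"] = conditional_skat(
                y, X, idx, G[:, keep], mafs=sel["maf"].to_numpy()[keep]
            ).p_value
            verdict = "independent rare-variant signal"
        else:
            row["p_conditional"] = np.nan
            verdict = "ineligible after pruning (pure tagging)"
        rows.append(row)
        print(f"region {k} ({label}): D' to index up to {max(dprimes):.2f}, "
              f"{len(retained)}/{G.shape[1]} variants retained -> {verdict}"
              + (f", conditional p = {row['p_conditional']:.3g}"
                 if np.isfinite(row["p_conditional"]) else ""))

    # probe-overlap conditioning on region 4
    k = 4
    sel = v[(v["region"] == k) & (v["block"] >= 0)]
    G = ds.dosages[:, sel.index]
    ovl_col = int(v.index[(v["region"] == k) & (v["id"].str.startswith("ovl"))][0])
    y = ds.methylation.loc[f"cg{k:08d}"].to_numpy(float)
    res = probe_overlap_conditioning(
        y, X, ds.dosages[:, ovl_col], G, mafs=sel["maf"].to_numpy()
    )
    rows.append(
        {
            "region": k,
            "scenario": "probe-overlapping rare variant",
            "n_variants": G.shape[1],
            "p_unconditional": res["p_unconditional"],
            "p_conditional": res["p_conditional"],
        }
    )
    print(f"region 4 (probe overlap): p {res['p_unconditional']:.3g} -> "
          f"{res['p_conditional']:.3g} after conditioning "
          f"({res['log10_attenuation']:.1f} decades of attenuation: the apparent "
          "signal was the overlapping variant)")

    pd.DataFrame(rows).to_csv(OUT / "conditional.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
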