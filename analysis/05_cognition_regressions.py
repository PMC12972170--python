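#!/usr/bin/env python
"""Cognition: composite z-scores, group comparisons, correlations and
interaction/education-trend regressions.

Computes per-domain composite z-scores against the Healthy reference and
the Kruskal-Wallis group comparison; the Spearman correlation between
posterior alpha2/alpha3 activity and MMSE across all participants; the
Education x alpha-activity interaction regression on the attention/
executive score in PDD with FDR-corrected simple slopes; and the per-group
continuous education-year trends of alpha activity.  Writes
results/regressions.json and a summary figure.
"""

import argparse
import json
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from lewyeeg import stats, synth

parser = argparse.ArgumentParser()
parser.add_argument("--activity", type=Path,
                    default=Path("results/activity.csv"))
parser.add_argument("--metadata", type=Path,
                    default=Path("results/cohort/cohort_metadata.csv"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

act = pd.read_csv(args.activity)
meta = pd.read_csv(args.metadata).set_index("subject_id")
meta = meta.loc[sorted(set(act["subject_id"]))]
out = {}

# composite cognitive z-scores vs the Healthy reference + Kruskal-Wallis
dom = meta[[f"score_{d}" for d in synth.DOMAINS]].rename(
    columns=lambda c: c.replace("score_", ""))
z = stats.composite_zscores(dom, meta["group"] == "Healthy", synth.DOMAINS)
out["kruskal"] = {}
print("Kruskal-Wallis on composite z-scores (Healthy vs PDD vs DLB):")
for d in synth.DOMAINS:
    res = stats.kruskal_multigroup(z[f"z_{d}"].to_numpy(),
                                   meta["group"].to_numpy())
    out["kruskal"][d] = {"H": res.h, "df": res.df, "p": res.p,
                         "posthoc": res.posthoc.to_dict(orient="records")}
    print(f"  {d}: H({res.df}) = {res.h:.1f}, p = {res.p:.2g}")

# posterior alpha vs MMSE, whole cohort
post = act[act["roi"].isin(["parietal", "occipital", "temporal", "limbic"])
           & act["band"].isin(["alpha2", "alpha3"])]
alpha_post = post.groupby("subject_id")["activity"].mean()
rho, p = stats.correlate(alpha_post.to_numpy(),
                         meta.loc[alpha_post.index, "mmse"].to_numpy(),
                         "spearman")
out["mmse_alpha_spearman"] = {"rho": rho, "p": p, "n": len(alpha_post)}
print(f"\nposterior alpha2/alpha3 vs MMSE: Spearman rho = {rho:.2f}, "
      f"p = {p:.2g} (n = {len(alpha_post)})")

# Education x occipital-alpha3 interaction on attention in PDD
occ_a3 = act[(act["roi"] == "occipital") & (act["band"] == "alpha3")]
df = occ_a3.merge(meta.reset_index(), on="subject_id")
pdd = df[df["group"] == "PDD"].rename(
    columns={"score_attention": "attention"}).copy()
res = stats.regress_interaction(pdd, "attention", "activity")
out["pdd_attention_interaction"] = res.to_dict()
s = res.simple_slopes.set_index("edu")
print(f"\nPDD attention ~ Edu x occipital alpha3: R2 = {res.r2:.2f}, "
      f"adj R2 = {res.adj_r2:.2f}, RSE = {res.rse:.2f}")
for lev in ("low", "high"):
    row = s.loc[lev]
    print(f"  Edu-{'-' if lev == 'low' else '+'} simple slope "
          f"{row['slope']:.2f} +/- {row['se']:.2f} "
          f"(FDR p = {row['p_fdr']:.3f})")

# continuous education-year trends of occipital alpha3 per group
out["education_trends"] = {}
print("\neducation-year trend of occipital alpha3 activity:")
for group in synth.GROUPS:
    gd = df[df["group"] == group]
    res_t = stats.education_trend(gd, "activity")
    row = res_t.simple_slopes.iloc[0]
    out["education_trends"][group] = res_t.to_dict()
    print(f"  {group}: {row['slope']:+.4f} +/- {row['se']:.4f} per year "
          f"(p = {row['p']:.3f})")

(args.out / "regressions.json").write_text(
    json.dumps(out, indent=1, default=str))

# summary figure: subgroup band profiles of global activity
fig, axes = plt.subplots(1, 3, figsize=(12, 3.5), sharey=True)
merged = act.merge(meta.reset_index()[["subject_id", "group", "edu"]],
                   on="subject_id")
for ax, group in zip(axes, synth.GROUPS):
    gd = merged[merged["group"] == group]
    prof = (gd.groupby(["edu", "band"], sort=False)["activity"]
            .mean().unstack(0))
    prof = prof.reindex(["delta", "theta", "alpha1", "alpha2", "alpha3",
                         "beta1", "beta2", "gamma"])
    ax.plot(prof.index, prof.get("low"), "o-", label="Edu-")
    ax.plot(prof.index, prof.get("high"), "s-", label="Edu+")
    ax.set_title(group)
    ax.tick_params(axis="x", rotation=45)
axes[0].set_ylabel("log10 normalized source activity")
axes[0].legend()
fig.tight_layout()
fig.savefig(args.out / "band_profiles.png", dpi=120)
print(f"\nwrote {args.out / 'regressions.json'} and band_profiles.png")
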