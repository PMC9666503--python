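"""Plain-text and figure summaries of a completed pipeline run."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402


def _read(run_dir: Path, name: str) -> pd.DataFrame:
    path = run_dir / f"{name}.tsv"
    if not path.exists():
        raise FileNotFoundError(f"result table missing from run directory: {path.name}")
    return pd.read_csv(path, sep="\t")


def report(run_dir, out_dir=None) -> Path:
    """Render ``summary.txt`` plus figures from a run directory's tables.

    Regeneration is idempotent: outputs depend only on the tables.  Returns
    the summary path.
    """
    run_dir = Path(run_dir)
    out = Path(out_dir) if out_dir else run_dir
    out.mkdir(parents=True, exist_ok=True)

    enrichment = _read(run_dir, "enrichment")
    median_ape = _read(run_dir, "median_ape")
    ratios_phylum = _read(run_dir, "ratios_phylum")
    diversity = _read(run_dir, "diversity")
    growth_by_phylum = _read(run_dir, "growth_by_phylum")
    efficiency = _read(run_dir, "efficiency")

    lines = ["qSIP run summary", "================", ""]
    n_active = int(enrichment["active"].sum())
    lines.append(f"ASV-treatment estimates: {len(enrichment)} "
                 f"({n_active} active, lower 90% CI > 0)")
    lines.append("")
    lines.append("Median APE of active taxa per treatment:")
    if len(median_ape):
        for r in median_ape.itertuples(index=False):
            lines.append(f"  {r.treatment:35s} {r.median_ape:8.2f} APE  (n={r.n_asvs})")
    else:
        lines.append("  no active taxa")
    lines.append("")
    lines.append("Phylum-level APE ratio tests (significant at adjusted p < 0.05):")
    sig = ratios_phylum[ratios_phylum.get("significant", pd.Series(dtype=bool)) == True]  # noqa: E712
    if len(sig):
        for r in sig.itertuples(index=False):
            lines.append(f"  {r.comparison:40s} {r.phylum:20s} "
                         f"mean ratio {r.mean_ratio:6.2f}  p_adj {r.p_adj:.4f}")
    else:
        lines.append("  none")
    lines.append("")
    lines.append("Growth efficiency per treatment:")
    if len(efficiency):
        for r in efficiency.itertuples(index=False):
            lines.append(f"  {r.treatment:35s} {r.efficiency:12.4g}")
    else:
        lines.append("  no CO2 data")

    summary = out / "summary.txt"
    summary.write_text("\n".join(lines) + "\n")

    # figures (skip panels whose table is empty, with an explicit note)
    fig, ax = plt.subplots(figsize=(7, 4))
    if len(median_ape):
        ax.bar(median_ape["treatment"], median_ape["median_ape"], color="#4477aa")
        ax.set_ylabel("median $^{18}$O APE (active taxa)")
        ax.tick_params(axis="x", rotation=60)
    else:
        ax.text(0.5, 0.5, "no active taxa", ha="center")
    fig.tight_layout()
    fig.savefig(out / "median_ape.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(8, 4.5))
    if len(growth_by_phylum):
        piv = growth_by_phylum.pivot_table(index="treatment", columns="phylum",
                                           values="gross_growth", fill_value=0.0)
        piv.plot.bar(stacked=True, ax=ax, colormap="tab20", legend=True)
        ax.set_ylabel("gross growth (16S copies g$^{-1}$)")
        ax.legend(fontsize=6, ncol=2)
    else:
        ax.text(0.5, 0.5, "no active taxa", ha="center")
    fig.tight_layout()
    fig.savefig(out / "growth_by_phylum.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(7, 4))
    if len(diversity):
        piv = diversity.pivot_table(index="treatment", columns="mode",
                                    values="inverse_simpson", aggfunc="median")
        piv.plot.bar(ax=ax)
        ax.set_ylabel("Inverse Simpson (median over tubes)")
        ax.tick_params(axis="x", rotation=60)
    fig.tight_layout()
    fig.savefig(out / "diversity.png", dpi=120)
    plt.close(fig)

    comps = list(ratios_phylum["comparison"].unique()) if len(ratios_phylum) else []
    if comps:
        fig, axes = plt.subplots(1, len(comps), figsize=(3.2 * len(comps), 4),
                                 squeeze=False, sharex=False)
        for ax, comp in zip(axes[0], comps):
            sub = ratios_phylum[ratios_phylum["comparison"] == comp]
            ax.barh(sub["phylum"], sub["mean_ratio"], xerr=sub["se"],
                    color=["#cc6677" if s else "#888888" for s in sub["significant"]])
            ax.axvline(1.0, color="k", lw=0.8)
            ax.set_title(comp, fontsize=7)
            ax.tick_params(labelsize=6)
        fig.tight_layout()
        fig.savefig(out / "ratio_panels.png", dpi=120)
        plt.close(fig)
    return summary
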