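#!/usr/bin/env python
"""Quick-look figures (optional; requires matplotlib).

Draws three summaries of the benchmark from the report tables: percent
contaminants vs dilution round, method accuracy across the series, and
inverse Simpson diversity before/after correction against the expected
value.  PNGs go under scratch/figures/ (plots are working artifacts, not
deliverables).
"""

from pathlib import Path

import pandas as pd

try:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
except ImportError:  # plotting is optional
    raise SystemExit("matplotlib not installed; skipping figures")

REPORTS = Path("results/reports")
DATA = Path("results/data")
OUT = Path("scratch/figures")

SHOW = ["negctrl", "abundance_0.01", "frequency_0.5",
        "sourcetracker_s1_case1", "sourcetracker_s2_case2"]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    summary = pd.read_csv(DATA / "summary.tsv", sep="\t", index_col=0)
    dilutions = summary.index[summary.index.str.startswith("D")]

    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(range(len(dilutions)), summary.loc[dilutions, "pct_contaminants"],
            "o-", label="simulated")
    ax.plot(range(len(dilutions)), summary.loc[dilutions, "analytic_pct"],
            "--", label="analytic f_d")
    ax.set_xlabel("dilution round")
    ax.set_ylabel("% contaminant reads")
    ax.legend()
    fig.tight_layout()
    fig.savefig(OUT / "contaminant_fraction.png", dpi=150)

    confusion = pd.read_csv(REPORTS / "confusion.tsv", sep="\t")
    fig, ax = plt.subplots(figsize=(6, 3.5))
    for method in SHOW:
        sub = confusion[confusion["method"] == method]
        ax.plot(sub["sample_id"], sub["accuracy"], "o-", label=method)
    ax.set_ylabel("classification accuracy")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(OUT / "accuracy_by_method.png", dpi=150)

    diversity = pd.read_csv(REPORTS / "diversity.tsv", sep="\t")
    inv = diversity[diversity["metric"] == "inv_simpson"]
    fig, ax = plt.subplots(figsize=(6, 3.5))
    for method in ["uncorrected"] + SHOW:
        sub = inv[inv["method"] == method]
        ax.plot(sub["sample_id"], sub["value"], "o-", label=method)
    expected = inv[inv["method"] == "uncorrected"]
    ax.plot(expected["sample_id"], expected["expected"], "k--", label="expected")
    ax.set_ylabel("inverse Simpson index")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(OUT / "diversity_by_method.png", dpi=150)

    print(f"wrote 3 figures -> {OUT}")


if __name__ == "__main__":
    main()
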