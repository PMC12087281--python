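"""Human-readable report and reference-line figures for a result bundle.

The report prints, per stratum, the per-CSO metric table (undefined ratios
shown as missing, never as infinity) and the cross-stratum medians/ranges; the
figures are bar charts of PPVs against the 7% workup-threshold line and of
tests-per-life against the 240 diagnostic-mammography benchmark, with bars
omitted where the quantity is flagged undefined.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .pipeline import RunBundle


def write_report(
    bundle: RunBundle,
    threshold: float = 0.07,
    benchmark: float = 240.0,
    figures: bool = True,
) -> Path:
    """Render ``report.txt`` (and per-stratum SVG figures) into the bundle dir.

    Regeneration is idempotent: the same bundle produces the same files.
    An empty bundle yields a minimal report without error.
    """
    out = Path(bundle.out_dir)
    lines: list[str] = ["Modeled CSO-directed workup performance", "=" * 44, ""]
    if not bundle.per_stratum:
        lines.append("(no strata completed)")
    for label, table in sorted(bundle.per_stratum.items()):
        lines.append(f"Stratum: {label}")
        lines.append("-" * (9 + len(label)))
        shown = table[
            ["n_pool", "ppv_any", "ppv_first", "ppv_remaining",
             "lives_first", "lives_post",
             "tests_per_life_first", "tests_per_life_post", "included"]
        ].copy()
        lines.append(shown.round(3).to_string(na_rep="-"))
        excluded = table.index[~table["included"]].tolist()
        if excluded:
            lines.append(f"excluded (not modelable): {', '.join(excluded)}")
        lines.append("")
    if bundle.summary is not None and len(bundle.summary):
        lines.append("Cross-stratum summaries (included CSOs only)")
        lines.append(bundle.summary.round(3).to_string(index=False))
        lines.append("")
    if bundle.failures:
        lines.append("Failed strata:")
        for label, cause in bundle.failures.items():
            lines.append(f"  {label}: {cause}")
    report_path = out / "report.txt"
    report_path.write_text("\n".join(lines) + "\n")

    if figures:
        for label, table in sorted(bundle.per_stratum.items()):
            _figures_for_stratum(table, label, out, threshold, benchmark)
    return report_path


def _figures_for_stratum(
    table: pd.DataFrame, label: str, out: Path, threshold: float, benchmark: float
) -> None:
    safe = label.replace(" ", "_")
    x = np.arange(len(table.index))

    fig, ax = plt.subplots(figsize=(8, 4))
    width = 0.27
    for i, (col, title) in enumerate(
        [("ppv_any", "any cancer"), ("ppv_first", "matched CSO"),
         ("ppv_remaining", "after rule-out")]
    ):
        vals = table[col].to_numpy(dtype=float)
        ax.bar(x + (i - 1) * width, np.nan_to_num(vals), width, label=f"PPV {title}")
    ax.axhline(threshold, ls="--", c="k", lw=1, label=f"{threshold:.0%} threshold")
    ax.set_xticks(x, table.index, rotation=60, ha="right", fontsize=7)
    ax.set_ylabel("PPV")
    ax.set_title(f"Diagnostic-chain PPVs — {label}")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / f"ppv_{safe}.svg")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(8, 4))
    for i, (col, title) in enumerate(
        [("tests_per_life_first", "site-directed"), ("tests_per_life_post", "general")]
    ):
        vals = table[col].to_numpy(dtype=float)
        mask = np.isfinite(vals)  # undefined ratios: bar omitted
        ax.bar(x[mask] + (i - 0.5) * 0.4, vals[mask], 0.4, label=title)
    ax.axhline(benchmark, ls="--", c="k", lw=1, label=f"{benchmark:.0f} (mammography)")
    ax.set_xticks(x, table.index, rotation=60, ha="right", fontsize=7)
    ax.set_ylabel("diagnostic tests per life saved")
    ax.set_title(f"Tests per life saved — {label}")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / f"tests_per_life_{safe}.svg")
    plt.close(fig)
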