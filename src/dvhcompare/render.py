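"""Paper-style text rendering of comparison results.

Human tables show ``value ± SEM`` with the SEM at two significant figures
and the value rounded to the SEM's last decimal; significant Wilcoxon
contrasts get a trailing ``*``; not-applicable cells read ``nan ± nan``.
Machine outputs (CSV) keep full precision and live in
:attr:`dvhcompare.compare.ComparisonResults.frame`.
"""

from __future__ import annotations

import math

import pandas as pd

__all__ = ["format_pm", "format_results", "results_to_table"]


def format_pm(value: float, sem: float, star: bool = False) -> str:
    """``value ± sem`` with SEM at 2 significant figures."""
    suffix = " *" if star else ""
    if math.isnan(value) or math.isnan(sem):
        return "nan ± nan"
    if sem == 0:
        return f"{value:.4g} ± 0{suffix}"
    exponent = math.floor(math.log10(abs(sem)))
    decimals = min(6, max(0, -(exponent - 1)))
    sem_r = round(sem, -(exponent - 1))
    return f"{value:.{decimals}f} ± {sem_r:.{decimals}f}{suffix}"


def results_to_table(results) -> pd.DataFrame:
    """Rounded, annotated table mirroring the comparison-table layout."""
    rows = []
    for r in results.rows:
        rec = {"structure": r.structure, "metric": r.metric}
        for m in results.model.modalities:
            rec[m] = format_pm(r.means[m], r.sems[m])
        for c in r.contrasts:
            rec[c.label] = format_pm(c.diff_mean, c.diff_sem, star=c.significant)
        rec["friedman_p"] = (
            f"{r.friedman.pvalue:.4g}" if r.friedman is not None else "nan"
        )
        rows.append(rec)
    return pd.DataFrame(rows)


def format_results(results, float_fmt: str = "{:.3g}") -> str:
    table = results_to_table(results)
    header = (
        f"Paired modality comparison (n = {results.rows[0].n_patients})\n"
        if results.rows
        else "Paired modality comparison (no rows)\n"
    )
    note = (
        "\nContrast cells: mean ± SEM of per-patient differences "
        "(relative % for dose metrics, absolute for NTCP); "
        "* marks Wilcoxon p < 0.05; nan ± nan marks not-applicable rows.\n"
    )
    return header + table.to_string(index=False) + note
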