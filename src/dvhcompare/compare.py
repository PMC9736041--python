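"""Paired three-modality comparison of dosimetric and NTCP quantities.

The central object is :class:`ModalityComparison`, a model built from a
long-format records table (patient, modality, structure, metric, value);
its :meth:`~ModalityComparison.fit` returns :class:`ComparisonResults`
carrying, per (structure, metric) row:

* per-modality mean ± SEM (SEM = sample SD / √n),
* per-patient pairwise differences aggregated per contrast — relative
  (percent, denominator = the second-named modality) for dose quantities,
  absolute for complication probabilities,
* the Friedman test across the three modalities and the Wilcoxon
  signed-rank post-test per contrast (both always reported; significance is
  the raw two-sided p < 0.05 with no multiplicity correction),
* exclusion accounting: a patient-metric is dropped from the statistical
  analysis when the value is below 1 Gy for **all three** modalities; a
  patient's relative difference for a contrast is dropped when **both**
  paired values are below 1 Gy; a cell with more than five dropped patients
  is reported not-applicable (NaN).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import FriedmanResult, WilcoxonResult, friedman_test, wilcoxon_signed_rank

__all__ = [
    "DOSE_METRICS_GY",
    "ContrastResult",
    "ComparisonRow",
    "ComparisonResults",
    "ModalityComparison",
    "relative_difference",
    "apply_exclusion_rules",
]

#: metrics measured in Gy, subject to the < 1 Gy exclusion rule
DOSE_METRICS_GY = frozenset({"Dmean", "D1", "D5", "D50", "D95", "D99", "Dmax", "Dmin"})

P_SIGNIFICANT = 0.05


def relative_difference(a, b):
    """Per-patient relative difference (a − b) / b × 100, in percent."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (a - b) / b * 100.0


def apply_exclusion_rules(
    values: np.ndarray, threshold: float = 1.0, max_excluded: int = 5
) -> tuple[np.ndarray, bool]:
    """Patient-level exclusion for one metric.

    ``values`` is (n_patients, n_modalities).  A patient is excluded when
    every modality value is below ``threshold`` (Gy).  Returns the retained
    mask and whether the whole row is not-applicable (more than
    ``max_excluded`` patients excluded).  Idempotent and order-independent.
    """
    values = np.asarray(values, dtype=float)
    retained = ~np.all(values < threshold, axis=1)
    n_excluded = int((~retained).sum())
    return retained, n_excluded > max_excluded


@dataclass(frozen=True)
class ContrastResult:
    """One pairwise contrast (e.g. helium vs proton) for one table row."""

    label: str  # "helium_vs_proton"
    kind: str  # "relative" (percent) or "absolute"
    diff_mean: float
    diff_sem: float
    wilcoxon: WilcoxonResult | None
    n_excluded: int
    not_applicable: bool

    @property
    def significant(self) -> bool:
        return self.wilcoxon is not None and self.wilcoxon.pvalue < P_SIGNIFICANT


@dataclass(frozen=True)
class ComparisonRow:
    """Paired summary for one (structure, metric) across the modalities."""

    structure: str
    metric: str
    n_patients: int
    means: dict[str, float]
    sems: dict[str, float]
    friedman: FriedmanResult | None
    contrasts: tuple[ContrastResult, ...]
    n_excluded: int  # patients failing the all-modalities rule
    excluded_row: bool  # statistical analysis not applicable

    def contrast(self, label: str) -> ContrastResult:
        for c in self.contrasts:
            if c.label == label:
                return c
        raise KeyError(label)


def _mean_sem(x: np.ndarray) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    n = x.size
    if n == 0:
        return float("nan"), float("nan")
    sem = float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return float(np.mean(x)), sem


class ModalityComparison:
    """Paired comparison model over a long-format records table.

    Parameters
    ----------
    records : DataFrame
        Columns ``patient_id``, ``modality``, ``structure``, ``metric``,
        ``value``.  Every (structure, metric) must be observed for the same
        patient set under every modality (the design is paired).
    kind : {"dose", "ntcp"}
        Dose rows report percent relative differences and apply the < 1 Gy
        exclusion to Gy-valued metrics; ntcp rows report absolute
        differences and no threshold exclusion.
    modalities, contrasts
        Modality order for reporting and the pairwise contrasts
        (each ``(a, b)`` reports a − b with b the denominator/comparator).
    """

    def __init__(
        self,
        records: pd.DataFrame,
        *,
        kind: str = "dose",
        modalities: tuple[str, ...] = ("helium", "proton", "photon"),
        contrasts: tuple[tuple[str, str], ...] = (("helium", "proton"), ("proton", "photon")),
        exclusion_threshold: float = 1.0,
        max_excluded: int = 5,
    ) -> None:
        required = {"patient_id", "modality", "structure", "metric", "value"}
        missing = required - set(records.columns)
        if missing:
            raise ValueError(f"records table lacks columns: {sorted(missing)}")
        if kind not in ("dose", "ntcp"):
            raise ValueError("kind must be 'dose' or 'ntcp'")
        self.records = records
        self.kind = kind
        self.modalities = tuple(modalities)
        self.contrasts = tuple(contrasts)
        self.exclusion_threshold = exclusion_threshold
        self.max_excluded = max_excluded

    # ------------------------------------------------------------------
    @classmethod
    def from_metric_records(cls, records, **kwargs) -> "ModalityComparison":
        """Build from a list of :class:`~dvhcompare.dosimetry.MetricRecord`."""
        from .dosimetry import records_to_frame

        return cls(records_to_frame(records), kind="dose", **kwargs)

    @classmethod
    def from_ntcp_records(cls, records, **kwargs) -> "ModalityComparison":
        """Build from :class:`~dvhcompare.ntcp.NTCPRecord` rows (metric = endpoint)."""
        from .ntcp import ntcp_records_to_frame

        frame = ntcp_records_to_frame(records).rename(columns={"endpoint": "metric"})
        frame = frame[["patient_id", "modality", "structure", "metric", "ntcp"]].rename(
            columns={"ntcp": "value"}
        )
        return cls(frame, kind="ntcp", **kwargs)

    # ------------------------------------------------------------------
    def _pivot(self, group: pd.DataFrame) -> pd.DataFrame:
        wide = group.pivot_table(
            index="patient_id", columns="modality", values="value", aggfunc="first"
        )
        missing = [m for m in self.modalities if m not in wide.columns]
        if missing:
            raise ValueError(f"missing modalities {missing} for a (structure, metric) group")
        wide = wide[list(self.modalities)]
        if wide.isna().any().any():
            raise ValueError("mismatched patient sets across modalities")
        return wide.sort_index()

    def fit(self) -> "ComparisonResults":
        rows = []
        for (structure, metric), group in self.records.groupby(
            ["structure", "metric"], sort=False
        ):
            wide = self._pivot(group)
            values = wide.to_numpy()
            n = values.shape[0]

            means = {m: float(values[:, i].mean()) for i, m in enumerate(self.modalities)}
            sems = {
                m: _mean_sem(values[:, i])[1] for i, m in enumerate(self.modalities)
            }

            thresholded = self.kind == "dose" and metric in DOSE_METRICS_GY
            if thresholded:
                retained, row_na = apply_exclusion_rules(
                    values, self.exclusion_threshold, self.max_excluded
                )
            else:
                retained, row_na = np.ones(n, dtype=bool), False
            n_excluded = int((~retained).sum())

            friedman = None
            if not row_na and retained.sum() >= 2:
                friedman = friedman_test(values[retained])

            contrasts = []
            for a, b in self.contrasts:
                ia, ib = self.modalities.index(a), self.modalities.index(b)
                va, vb = values[:, ia], values[:, ib]
                if self.kind == "ntcp":
                    diffs = va - vb
                    pair_keep = np.ones(n, dtype=bool)
                    kind = "absolute"
                else:
                    pair_keep = ~(
                        (va < self.exclusion_threshold) & (vb < self.exclusion_threshold)
                    ) if thresholded else np.ones(n, dtype=bool)
                    pair_keep &= vb != 0
                    diffs = relative_difference(va, vb)
                    kind = "relative"
                pair_excluded = int((~pair_keep).sum())
                pair_na = pair_excluded > self.max_excluded
                if pair_na or pair_keep.sum() == 0:
                    dm, ds = float("nan"), float("nan")
                else:
                    dm, ds = _mean_sem(diffs[pair_keep])
                wres = None
                if not row_na and retained.sum() >= 2:
                    wres = wilcoxon_signed_rank(va[retained], vb[retained])
                contrasts.append(
                    ContrastResult(
                        label=f"{a}_vs_{b}",
                        kind=kind,
                        diff_mean=dm,
                        diff_sem=ds,
                        wilcoxon=wres,
                        n_excluded=pair_excluded,
                        not_applicable=pair_na,
                    )
                )

            rows.append(
                ComparisonRow(
                    structure=structure,
                    metric=metric,
                    n_patients=n,
                    means=means,
                    sems=sems,
                    friedman=friedman,
                    contrasts=tuple(contrasts),
                    n_excluded=n_excluded,
                    excluded_row=row_na,
                )
            )
        return ComparisonResults(rows=tuple(rows), model=self)


@dataclass(frozen=True)
class ComparisonResults:
    """Fitted paired-comparison results; one row per (structure, metric)."""

    rows: tuple[ComparisonRow, ...]
    model: ModalityComparison = field(repr=False)

    def row(self, structure: str, metric: str) -> ComparisonRow:
        for r in self.rows:
            if r.structure == structure and r.metric == metric:
                return r
        raise KeyError((structure, metric))

    @property
    def frame(self) -> pd.DataFrame:
        """Flat full-precision DataFrame of every row and contrast."""
        out = []
        for r in self.rows:
            rec: dict = {
                "structure": r.structure,
                "metric": r.metric,
                "n_patients": r.n_patients,
                "n_excluded": r.n_excluded,
                "excluded_row": r.excluded_row,
                "friedman_p": r.friedman.pvalue if r.friedman else float("nan"),
            }
            for m in self.model.modalities:
                rec[f"mean_{m}"] = r.means[m]
                rec[f"sem_{m}"] = r.sems[m]
            for c in r.contrasts:
                rec[f"diff_{c.label}"] = c.diff_mean
                rec[f"diff_sem_{c.label}"] = c.diff_sem
                rec[f"p_{c.label}"] = c.wilcoxon.pvalue if c.wilcoxon else float("nan")
                rec[f"sig_{c.label}"] = c.significant
            out.append(rec)
        return pd.DataFrame(out)

    def summary(self, float_fmt: str = "{:.3g}") -> str:
        """Human-readable comparison table (paper-style layout).

        Cells are ``mean ± SEM``; a trailing ``*`` marks a significant
        Wilcoxon contrast (p < 0.05); not-applicable cells read ``nan ± nan``.
        """
        from .render import format_results  # deferred: rendering is optional

        return format_results(self, float_fmt=float_fmt)
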