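"""Plain-text DVH file dialect.

One file per (patient, modality).  Header block of ``# key: value`` lines,
then one block per structure introduced by ``## structure:`` lines, followed
by CSV rows ``dose_Gy,relative_volume`` printed with 6 decimal places::

    # patient: P01
    # modality: proton
    # prescription_Gy: 54.000000
    # fractions: 30
    # dose_per_fraction_Gy: 1.800000
    ## structure: ctv
    ## volume_cm3: 60.000000
    ## kind: cumulative
    0.000000,1.000000
    ...

The dialect is UTF-8, diff-able, and trivially writable from any planning
system export.  Reading a file produced by :func:`write_dvh_file` yields a
:class:`~dvhcompare.curves.PlanSet` equal to the one written, at the stated
6-decimal precision.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np

from .curves import DVHCurve, DVHValidationError, PlanSet

__all__ = [
    "DVHParseError",
    "MalformedHeaderError",
    "MissingMetadataError",
    "read_dvh_file",
    "write_dvh_file",
]

_HEADER_KEYS = ("patient", "modality", "prescription_Gy", "fractions", "dose_per_fraction_Gy")


class DVHParseError(ValueError):
    """The file does not conform to the DVH dialect."""


class MalformedHeaderError(DVHParseError):
    """A header or structure-block line cannot be parsed."""


class MissingMetadataError(DVHParseError):
    """Required prescription or structure metadata is absent."""


def _parse_kv(line: str, prefix: str) -> tuple[str, str]:
    body = line[len(prefix):].strip()
    if ":" not in body:
        raise MalformedHeaderError(f"cannot parse header line: {line!r}")
    key, _, value = body.partition(":")
    return key.strip(), value.strip()


def read_dvh_file(path: os.PathLike | str) -> PlanSet:
    """Read one dialect DVH file into a validated :class:`PlanSet`.

    Raises
    ------
    MalformedHeaderError
        A header line cannot be parsed.
    MissingMetadataError
        Prescription metadata or a structure attribute is missing.
    DVHParseError
        A data row is malformed.
    DVHValidationError
        A curve violates its invariants (non-monotone cumulative column,
        negative volume, ...).
    """
    header: dict[str, str] = {}
    blocks: list[dict] = []
    current: dict | None = None

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("##"):
                key, value = _parse_kv(line, "##")
                if key == "structure":
                    current = {"structure": value, "rows": []}
                    blocks.append(current)
                elif current is None:
                    raise MalformedHeaderError(
                        f"line {lineno}: {key!r} before any '## structure:' block"
                    )
                else:
                    current[key] = value
            elif line.startswith("#"):
                key, value = _parse_kv(line, "#")
                header[key] = value
            else:
                if current is None:
                    raise DVHParseError(f"line {lineno}: data row outside a structure block")
                parts = line.split(",")
                if len(parts) != 2:
                    raise DVHParseError(f"line {lineno}: expected 'dose_Gy,relative_volume'")
                try:
                    current["rows"].append((float(parts[0]), float(parts[1])))
                except ValueError as exc:
                    raise DVHParseError(f"line {lineno}: non-numeric data row") from exc

    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise MissingMetadataError(f"missing header keys: {', '.join(missing)}")

    curves = {}
    for block in blocks:
        label = block["structure"]
        for attr in ("volume_cm3", "kind"):
            if attr not in block:
                raise MissingMetadataError(f"structure {label!r}: missing '{attr}'")
        rows = np.asarray(block["rows"], dtype=float)
        if rows.size == 0:
            raise DVHParseError(f"structure {label!r}: no data rows")
        kind = block["kind"]
        dose = rows[:, 0]
        vol = rows[:, 1]
        if kind == "differential":
            # rows carry one fraction per bin; the final row closes the last
            # bin edge and must have volume 0
            edges, frac = dose, vol[:-1]
            if abs(vol[-1]) > 1e-12:
                raise DVHParseError(
                    f"structure {label!r}: differential block must end with a 0-volume edge row"
                )
            curve_vol = frac
        else:
            edges, curve_vol = dose, vol
        curves[label] = DVHCurve(
            patient_id=header["patient"],
            modality=header["modality"],
            structure=label,
            kind=kind,
            dose_edges=edges,
            volume=curve_vol,
            abs_volume=float(block["volume_cm3"]),
        )

    try:
        n_fractions = int(header["fractions"])
        prescription = float(header["prescription_Gy"])
        per_fraction = float(header["dose_per_fraction_Gy"])
    except ValueError as exc:
        raise MalformedHeaderError("non-numeric prescription metadata") from exc

    return PlanSet(
        patient_id=header["patient"],
        modality=header["modality"],
        prescription_dose=prescription,
        n_fractions=n_fractions,
        dose_per_fraction=per_fraction,
        curves=curves,
    )


def write_dvh_file(plan: PlanSet, path: os.PathLike | str) -> None:
    """Write a PlanSet in the dialect; deterministic byte-for-byte output."""
    lines: list[str] = [
        f"# patient: {plan.patient_id}",
        f"# modality: {plan.modality}",
        f"# prescription_Gy: {plan.prescription_dose:.6f}",
        f"# fractions: {plan.n_fractions}",
        f"# dose_per_fraction_Gy: {plan.dose_per_fraction:.6f}",
    ]
    for label in plan.structures:
        curve = plan[label]
        lines.append(f"## structure: {label}")
        lines.append(f"## volume_cm3: {curve.abs_volume:.6f}")
        lines.append(f"## kind: {curve.kind}")
        if curve.kind == "cumulative":
            pairs: Iterable[tuple[float, float]] = zip(curve.dose_edges, curve.volume)
        else:
            # one fraction per bin, closing edge row with volume 0
            pairs = zip(curve.dose_edges, np.append(curve.volume, 0.0))
        lines.extend(f"{d:.6f},{v:.6f}" for d, v in pairs)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")
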