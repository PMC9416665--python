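"""FASTA/TSV input-output and NMR-comparison helpers.

TSV dialect: tab-separated, '#'-prefixed header line, '.' decimal,
6 significant digits.  Profiles round-trip losslessly at that precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .core import PropensityProfile


@dataclass(frozen=True)
class FastaRecord:
    record_id: str
    description: str
    sequence: str


def read_fasta(path: str | Path) -> list[FastaRecord]:
    """All records of a FASTA file, in input order."""
    path = Path(path)
    records = [
        FastaRecord(rec.id, rec.description, str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    for rec in records:
        if not rec.sequence:
            raise ValueError(f"{path}: record {rec.record_id!r} has an empty sequence")
    return records


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def write_profile(path: str | Path, profile: PropensityProfile) -> None:
    """Write a propensity profile as TSV (index, residue, class, weight, propensity)."""
    with open(path, "w") as fh:
        if profile.record_id:
            fh.write(f"# record: {profile.record_id}\n")
        fh.write("#index\tresidue\tclass\tweight\tpropensity\n")
        for idx, aa, cls, w, p in zip(
            profile.indices,
            profile.sequence,
            profile.classes,
            profile.weights,
            profile.propensities,
        ):
            fh.write(f"{idx}\t{aa}\t{cls.symbol}\t{_fmt(w)}\t{_fmt(p)}\n")


@dataclass(frozen=True)
class ContactProfile:
    """Observed per-residue contact probabilities."""

    indices: np.ndarray
    values: np.ndarray
    residues: tuple[str, ...] | None = None


def read_profile(path: str | Path, value_range: tuple[float, float] | None = (0.0, 1.0)) -> ContactProfile:
    """Read a per-residue TSV: index, [residue,] value. Validates the range."""
    path = Path(path)
    indices, values, residues = [], [], []
    has_residue = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if len(fields) == 2:
                    row_has_res = False
                    idx, val = int(fields[0]), float(fields[1])
                    res = None
                elif len(fields) >= 3:
                    row_has_res = True
                    idx, res, val = int(fields[0]), fields[1], float(fields[-1])
                else:
                    raise ValueError("expected 2+ tab-separated fields")
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from None
            if has_residue is None:
                has_residue = row_has_res
            if not math.isfinite(val):
                raise ValueError(f"{path}:{lineno}: non-finite value")
            if value_range is not None and not value_range[0] <= val <= value_range[1]:
                raise ValueError(
                    f"{path}:{lineno}: value {val} outside "
                    f"[{value_range[0]}, {value_range[1]}]"
                )
            indices.append(idx)
            values.append(val)
            if res is not None:
                residues.append(res)
    if not indices:
        raise ValueError(f"{path}: no data rows")
    return ContactProfile(
        indices=np.asarray(indices),
        values=np.asarray(values, dtype=float),
        residues=tuple(residues) if residues else None,
    )


def write_series(path: str | Path, indices, values, header: tuple[str, str]) -> None:
    """Write a two-column TSV (e.g. z_tip in, contact probability out)."""
    with open(path, "w") as fh:
        fh.write(f"#{header[0]}\t{header[1]}\n")
        for idx, val in zip(indices, values):
            fh.write(f"{idx}\t{_fmt(val)}\n")


def read_ztip(path: str | Path) -> ContactProfile:
    """Read a (index, z_tip) TSV; heights are unbounded."""
    return read_profile(path, value_range=None)


def combined_shift_perturbation(
    delta_H,
    delta_N,
    nitrogen_weight: float = 0.154,
    floor: float | None = None,
):
    """Composite amide chemical-shift perturbation.

    sqrt(delta_H**2 + nitrogen_weight * delta_N**2); values below
    ``floor`` (if given) are set to 0, mirroring the treatment of shifts
    within experimental error.
    """
    if nitrogen_weight <= 0:
        raise ValueError("nitrogen_weight must be > 0")
    dH = np.asarray(delta_H, dtype=float)
    dN = np.asarray(delta_N, dtype=float)
    if not (np.all(np.isfinite(dH)) and np.all(np.isfinite(dN))):
        raise ValueError("inputs must be finite")
    out = np.sqrt(dH**2 + nitrogen_weight * dN**2)
    if floor is not None:
        out = np.where(out < floor, 0.0, out)
    return out if out.ndim else float(out)
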