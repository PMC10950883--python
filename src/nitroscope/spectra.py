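"""Spectrum and PSM-table I/O: MGF, FASTA and TSV, via pyteomics + pandas.

Defines the two shared data records — :class:`Spectrum` and
:class:`PSMRecord` — and the readers/writers every pipeline stage uses.
Peptide and protein positions are 1-based throughout; an "N-terminal
nitroY" is a nitroY modification at peptide position 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from pyteomics import mgf as _pmgf

from .masses import (
    DEFAULT_MODIFICATIONS,
    InputError,
    ModificationDefinition,
    Peptidoform,
)

__all__ = [
    "Spectrum",
    "PSMRecord",
    "RejectedRow",
    "ParseError",
    "SchemaError",
    "read_mgf",
    "write_mgf",
    "read_fasta",
    "write_fasta",
    "read_psm_table",
    "write_psm_table",
    "psm_records_from_frame",
    "format_modifications",
]

PSM_COLUMNS = (
    "sequence",
    "modifications",
    "protein",
    "start",
    "spectrum_id",
    "antibody",
    "mode",
    "replicate",
)

ENRICHMENT_MODES = ("protein_level", "peptide_level")


class ParseError(ValueError):
    """A malformed spectrum block or file."""


class SchemaError(ValueError):
    """A tabular input missing required columns."""


@dataclass
class Spectrum:
    """A centroided peak list with precursor metadata.

    Peaks are stored sorted ascending by m/z; duplicate m/z values are merged
    by intensity summation at construction so downstream one-to-one peak
    matching is well defined.
    """

    identifier: str
    precursor_mz: float
    precursor_charge: int
    mz: np.ndarray
    intensity: np.ndarray
    provenance: str = "experimental"

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise ParseError(f"spectrum {self.identifier!r}: peak arrays mismatch")
        if np.any(inten < 0):
            raise ParseError(f"spectrum {self.identifier!r}: negative intensity")
        order = np.argsort(mz, kind="stable")
        mz, inten = mz[order], inten[order]
        if mz.size:
            uniq, inverse = np.unique(mz, return_inverse=True)
            if uniq.size != mz.size:
                inten = np.bincount(inverse, weights=inten, minlength=uniq.size)
                mz = uniq
        self.mz, self.intensity = mz, inten

    def __len__(self) -> int:
        return int(self.mz.size)

    @property
    def base_peak_intensity(self) -> float:
        return float(self.intensity.max()) if len(self) else 0.0

    def replace(self, **kw) -> "Spectrum":
        data = dict(
            identifier=self.identifier,
            precursor_mz=self.precursor_mz,
            precursor_charge=self.precursor_charge,
            mz=self.mz,
            intensity=self.intensity,
            provenance=self.provenance,
        )
        data.update(kw)
        return Spectrum(**data)


def read_mgf(path) -> list[Spectrum]:
    """Read an MGF file into a list of :class:`Spectrum` (TITLE = identifier)."""
    path = Path(path)
    spectra: list[Spectrum] = []
    with _pmgf.MGF(str(path), convert_arrays=1) as reader:
        for i, block in enumerate(reader):
            params = block.get("params", {})
            title = str(params.get("title", f"{path.stem}.{i}"))
            if "pepmass" not in params:
                raise ParseError(f"block {title!r} (#{i + 1}) missing PEPMASS")
            pepmass = params["pepmass"]
            prec_mz = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
            charge = params.get("charge")
            if charge:
                z = int(charge[0]) if isinstance(charge, (tuple, list)) else int(charge)
            else:
                z = 0
            spectra.append(
                Spectrum(
                    identifier=title,
                    precursor_mz=prec_mz,
                    precursor_charge=z,
                    mz=block["m/z array"],
                    intensity=block["intensity array"],
                )
            )
    if not spectra:
        warnings.warn(f"{path}: no spectra found", stacklevel=2)
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path) -> None:
    """Write spectra to MGF; round-trips m/z and intensity at ~6 decimals."""
    entries = []
    for s in spectra:
        params = {"title": s.identifier, "pepmass": s.precursor_mz}
        if s.precursor_charge:
            params["charge"] = s.precursor_charge
        entries.append(
            {"m/z array": s.mz, "intensity array": s.intensity, "params": params}
        )
    with open(path, "w") as fh:
        _pmgf.write(entries, fh)


def _primary_accession(description: str) -> str:
    head = description.split()[0]
    if head.count("|") >= 2:  # e.g. sp|P07437|TBB5_HUMAN
        return head.split("|")[1]
    return head


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA into ``{accession: uppercase sequence}``.

    Headers are reduced to the primary accession; ``*`` stop symbols are
    stripped with a warning; duplicate accessions are an error.
    """
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        acc = _primary_accession(record.description or record.id)
        if acc in out:
            raise InputError(f"duplicate accession {acc!r} in {path}")
        seq = str(record.seq).upper()
        if "*" in seq:
            warnings.warn(f"{acc}: stripped stop symbol '*'", stacklevel=2)
            seq = seq.replace("*", "")
        out[acc] = seq
    return out


def write_fasta(proteins: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for acc, seq in proteins.items():
            fh.write(f">{acc}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


@dataclass(frozen=True)
class PSMRecord:
    """One peptide-spectrum match row: peptidoform + provenance metadata."""

    peptidoform: Peptidoform
    protein_accession: str
    peptide_start: int  # 1-based index of the peptide in the protein
    spectrum_id: str
    antibody: str
    enrichment_mode: str  # protein_level | peptide_level
    replicate: int


@dataclass(frozen=True)
class RejectedRow:
    """A diagnosed PSM-table rejection; parsing is total (valid + rejected = input)."""

    row: int  # 1-based data-row number
    reason: str


def format_modifications(mods: Sequence[tuple[int, str]]) -> str:
    return ";".join(f"{p}:{n}" for p, n in mods)


def _parse_modifications(text) -> list[tuple[int, str]]:
    if text is None or (isinstance(text, float) and np.isnan(text)):
        return []
    text = str(text).strip()
    if not text or text == "-":
        return []
    mods = []
    for token in text.split(";"):
        token = token.strip()
        if not token:
            continue
        pos, _, name = token.partition(":")
        if not name:
            raise InputError(f"modification token {token!r} not in 'pos:name' form")
        mods.append((int(pos), name))
    return mods


def read_psm_table(
    path,
    fasta: Mapping[str, str] | None = None,
    mods: Mapping[str, ModificationDefinition] = DEFAULT_MODIFICATIONS,
) -> tuple[list[PSMRecord], list[RejectedRow]]:
    """Read a PSM TSV into validated records plus row-numbered rejections.

    Required columns: ``sequence, modifications, protein, start, spectrum_id,
    antibody, mode, replicate``. Modification strings are ``pos:name`` pairs
    joined by ``;`` (1-based positions within the peptide). When ``fasta`` is
    given, the peptide must occur at the stated offset of its protein.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return psm_records_from_frame(frame, fasta=fasta, mods=mods)


def psm_records_from_frame(
    frame: pd.DataFrame,
    fasta: Mapping[str, str] | None = None,
    mods: Mapping[str, ModificationDefinition] = DEFAULT_MODIFICATIONS,
) -> tuple[list[PSMRecord], list[RejectedRow]]:
    missing = [c for c in PSM_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"PSM table missing columns: {missing}")
    charge_col = frame["charge"] if "charge" in frame.columns else None

    records: list[PSMRecord] = []
    rejected: list[RejectedRow] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        try:
            mode = str(row.mode)
            if mode not in ENRICHMENT_MODES:
                raise InputError(f"unknown enrichment mode {mode!r}")
            antibody = str(row.antibody)
            if not antibody:
                raise InputError("empty antibody label")
            charge = int(charge_col.iloc[i - 1]) if charge_col is not None else 2
            p = Peptidoform(
                sequence=str(row.sequence),
                modifications=tuple(_parse_modifications(row.modifications)),
                charge=charge,
            )
            p.validate_targets(mods)
            start = int(row.start)
            if start < 1:
                raise InputError(f"peptide start {start} must be >= 1")
            acc = str(row.protein)
            if fasta is not None:
                if acc not in fasta:
                    raise InputError(f"protein {acc!r} absent from FASTA")
                segment = fasta[acc][start - 1 : start - 1 + len(p.sequence)]
                if segment != p.sequence:
                    raise InputError(
                        f"peptide does not occur at {acc}:{start} in FASTA"
                    )
            records.append(
                PSMRecord(
                    peptidoform=p,
                    protein_accession=acc,
                    peptide_start=start,
                    spectrum_id=str(row.spectrum_id),
                    antibody=antibody,
                    enrichment_mode=mode,
                    replicate=int(row.replicate),
                )
            )
        except (InputError, ValueError) as exc:
            rejected.append(RejectedRow(row=i, reason=str(exc)))
    return records, rejected


def write_psm_table(records: Iterable[PSMRecord], path) -> None:
    rows = [
        {
            "sequence": r.peptidoform.sequence,
            "modifications": format_modifications(r.peptidoform.modifications),
            "protein": r.protein_accession,
            "start": r.peptide_start,
            "spectrum_id": r.spectrum_id,
            "antibody": r.antibody,
            "mode": r.enrichment_mode,
            "replicate": r.replicate,
            "charge": r.peptidoform.charge,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(PSM_COLUMNS) + ["charge"]).to_csv(
        path, sep="\t", index=False
    )
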