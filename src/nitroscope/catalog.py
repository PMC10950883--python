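"""Nitro-site cataloging and its summary analyses.

From validated PSM records this module builds the site catalog (peptide
coordinates lifted to protein coordinates, every site checked to be a
tyrosine), then computes the study-level summaries: the fraction of
peptidoforms carrying the nitro group at the peptide N-terminus per
antibody and enrichment mode, cross-antibody overlap (Venn regions and
subset intersections), union catalog counts, and flanking-sequence motif
matrices for logo construction.

Counting unit: a "peptide" is a distinct modified peptidoform — the peptide
sequence together with its set of nitroY positions — ignoring charge and
replicate. A "protein" is the reported accession.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .masses import InputError, Peptidoform
from .spectra import PSMRecord, RejectedRow

__all__ = [
    "NitroSiteRecord",
    "OverlapSummary",
    "MotifMatrix",
    "GAP",
    "build_catalog",
    "catalog_frame",
    "n_terminal_fraction",
    "overlap_summary",
    "union_catalog",
    "extract_windows",
    "motif_matrix",
    "background_frequencies",
]

#: Terminal-gap symbol used when a motif window runs off the protein end.
GAP = "-"

RESIDUES = tuple("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class NitroSiteRecord:
    """One localized nitrotyrosine site observation.

    ``protein_position`` is the 1-based protein residue index of the nitrated
    tyrosine: ``peptide_start + peptide_position - 1``.
    """

    protein_accession: str
    protein_position: int
    peptidoform: Peptidoform
    peptide_start: int
    peptide_position: int
    antibody: str
    enrichment_mode: str
    replicate: int

    @property
    def peptidoform_key(self) -> tuple[str, tuple[int, ...]]:
        """Distinct-peptide identity: sequence + nitroY position set."""
        return (self.peptidoform.sequence, self.peptidoform.nitro_positions)

    @property
    def n_terminal(self) -> bool:
        return self.peptide_position == 1


def build_catalog(
    psms: Sequence[PSMRecord],
    fasta: Mapping[str, str] | None = None,
    nitro_modification: str = "nitroY",
) -> tuple[list[NitroSiteRecord], list[RejectedRow]]:
    """One site record per (PSM, nitro modification position).

    With a FASTA supplied, sites whose protein-coordinate residue is not a
    tyrosine are rejected with a diagnostic naming accession and position.
    """
    records: list[NitroSiteRecord] = []
    rejected: list[RejectedRow] = []
    for i, psm in enumerate(psms, start=1):
        for pos, name in psm.peptidoform.modifications:
            if name != nitro_modification:
                continue
            prot_pos = psm.peptide_start + pos - 1
            if fasta is not None:
                seq = fasta.get(psm.protein_accession)
                if seq is None:
                    rejected.append(
                        RejectedRow(i, f"protein {psm.protein_accession!r} not in FASTA")
                    )
                    continue
                if prot_pos > len(seq) or seq[prot_pos - 1] != "Y":
                    found = seq[prot_pos - 1] if prot_pos <= len(seq) else "<end>"
                    rejected.append(
                        RejectedRow(
                            i,
                            f"{psm.protein_accession}:{prot_pos} is {found}, not Y",
                        )
                    )
                    continue
            records.append(
                NitroSiteRecord(
                    protein_accession=psm.protein_accession,
                    protein_position=prot_pos,
                    peptidoform=psm.peptidoform,
                    peptide_start=psm.peptide_start,
                    peptide_position=pos,
                    antibody=psm.antibody,
                    enrichment_mode=psm.enrichment_mode,
                    replicate=psm.replicate,
                )
            )
    return records, rejected


def catalog_frame(catalog: Sequence[NitroSiteRecord]) -> pd.DataFrame:
    """Tabular view of the catalog (one row per site record)."""
    return pd.DataFrame(
        {
            "protein": [r.protein_accession for r in catalog],
            "protein_position": [r.protein_position for r in catalog],
            "sequence": [r.peptidoform.sequence for r in catalog],
            "peptide_start": [r.peptide_start for r in catalog],
            "peptide_position": [r.peptide_position for r in catalog],
            "peptidoform": [
                f"{r.peptidoform_key[0]}@{','.join(map(str, r.peptidoform_key[1]))}"
                for r in catalog
            ],
            "n_terminal": [r.n_terminal for r in catalog],
            "antibody": [r.antibody for r in catalog],
            "mode": [r.enrichment_mode for r in catalog],
            "replicate": [r.replicate for r in catalog],
        }
    )


def n_terminal_fraction(
    catalog: Sequence[NitroSiteRecord],
    group_by: Sequence[str] = ("antibody", "mode"),
) -> pd.DataFrame:
    """Per-group fraction of distinct nitro peptidoforms with nitroY at position 1.

    Returns a DataFrame with the grouping columns plus ``n_peptidoforms``,
    ``n_n_terminal`` and ``fraction``. Groups with no peptidoforms are
    omitted (with a warning only if the catalog itself was empty).
    """
    if not catalog:
        warnings.warn("empty catalog: no N-terminal fractions to report", stacklevel=2)
        return pd.DataFrame(
            columns=list(group_by) + ["n_peptidoforms", "n_n_terminal", "fraction"]
        )
    df = catalog_frame(catalog)
    rows = []
    for key, sub in df.groupby(list(group_by), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        pep = sub.drop_duplicates("peptidoform")
        n = len(pep)
        n1 = int(pep["n_terminal"].sum())
        rows.append(dict(zip(group_by, key), n_peptidoforms=n, n_n_terminal=n1,
                         fraction=n1 / n))
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class OverlapSummary:
    """Cross-antibody overlap of captured proteins or peptidoforms.

    ``region_counts`` are exclusive Venn-region counts (elements seen by
    exactly that antibody set); ``intersection_counts`` are plain subset
    intersections. Exclusive regions partition the union, so their counts sum
    to ``union_count`` (inclusion–exclusion consistency).
    """

    unit: str
    sets: Mapping[str, frozenset]
    region_counts: Mapping[frozenset, int]
    intersection_counts: Mapping[frozenset, int]
    union_count: int

    @property
    def antibodies(self) -> tuple[str, ...]:
        return tuple(sorted(self.sets))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for subset in sorted(self.intersection_counts, key=lambda s: (len(s), sorted(s))):
            rows.append(
                {
                    "antibodies": "&".join(sorted(subset)),
                    "n_antibodies": len(subset),
                    "exclusive_count": self.region_counts.get(subset, 0),
                    "intersection_count": self.intersection_counts[subset],
                }
            )
        return pd.DataFrame(rows)


def overlap_summary(
    catalog: Sequence[NitroSiteRecord],
    unit: str = "protein",
    mode: str | None = None,
) -> OverlapSummary:
    """Exact overlap structure of per-antibody capture sets.

    ``unit`` is ``protein`` or ``peptidoform``; ``mode`` restricts to one
    enrichment mode. Needs at least two antibodies present.
    """
    if unit not in ("protein", "peptidoform"):
        raise InputError(f"unknown overlap unit {unit!r}")
    records = [r for r in catalog if mode is None or r.enrichment_mode == mode]
    sets: dict[str, set] = {}
    for r in records:
        element = r.protein_accession if unit == "protein" else r.peptidoform_key
        sets.setdefault(r.antibody, set()).add(element)
    if len(sets) < 2:
        raise InputError(
            f"overlap needs >= 2 antibodies, found {sorted(sets)} "
            f"(unit={unit!r}, mode={mode!r})"
        )
    antibodies = sorted(sets)
    universe = set().union(*sets.values())
    membership: dict = {}
    for el in universe:
        membership[el] = frozenset(a for a in antibodies if el in sets[a])
    region_counts: dict[frozenset, int] = {}
    for m in membership.values():
        region_counts[m] = region_counts.get(m, 0) + 1
    intersection_counts: dict[frozenset, int] = {}
    for k in range(1, len(antibodies) + 1):
        for combo in combinations(antibodies, k):
            inter = set.intersection(*(sets[a] for a in combo))
            intersection_counts[frozenset(combo)] = len(inter)
    return OverlapSummary(
        unit=unit,
        sets={a: frozenset(s) for a, s in sets.items()},
        region_counts=region_counts,
        intersection_counts=intersection_counts,
        union_count=len(universe),
    )


def union_catalog(catalog: Sequence[NitroSiteRecord]) -> dict:
    """Distinct peptidoform and protein counts per enrichment mode and overall."""
    by_mode: dict[str, dict] = {}
    modes = sorted({r.enrichment_mode for r in catalog})
    for m in modes:
        recs = [r for r in catalog if r.enrichment_mode == m]
        by_mode[m] = {
            "peptidoforms": len({r.peptidoform_key for r in recs}),
            "proteins": len({r.protein_accession for r in recs}),
        }
    return {
        "by_mode": by_mode,
        "overall": {
            "peptidoforms": len({r.peptidoform_key for r in catalog}),
            "proteins": len({r.protein_accession for r in catalog}),
        },
    }


def extract_windows(
    catalog: Sequence[NitroSiteRecord],
    fasta: Mapping[str, str],
    k: int = 7,
    distinct_sites: bool = True,
) -> list[str]:
    """Length-(2k+1) protein-sequence windows centered on each nitrated Y.

    Windows come from the protein (not the peptide) and are padded with the
    terminal-gap symbol where they run past either protein end. With
    ``distinct_sites`` each (protein, position) contributes once.
    """
    seen: set[tuple[str, int]] = set()
    windows: list[str] = []
    for r in catalog:
        key = (r.protein_accession, r.protein_position)
        if distinct_sites:
            if key in seen:
                continue
            seen.add(key)
        seq = fasta[r.protein_accession]
        c = r.protein_position - 1
        left = seq[max(0, c - k) : c]
        right = seq[c + 1 : c + 1 + k]
        windows.append(
            GAP * (k - len(left)) + left + seq[c] + right + GAP * (k - len(right))
        )
    return windows


def background_frequencies(fasta: Mapping[str, str]) -> pd.Series:
    """Residue frequencies over all FASTA sequences (the log-odds background)."""
    counts = {aa: 0 for aa in RESIDUES}
    for seq in fasta.values():
        for aa in seq:
            if aa in counts:
                counts[aa] += 1
    total = sum(counts.values())
    if total == 0:
        raise InputError("empty FASTA: no background frequencies")
    return pd.Series({aa: c / total for aa, c in counts.items()})


@dataclass(frozen=True)
class MotifMatrix:
    """Position x residue counts/frequencies/log2-odds for nitroY-centered windows.

    Rows are positions -k..+k relative to the nitrated tyrosine; columns are
    the 20 residues plus the terminal-gap symbol. ``log_odds`` is
    log2(observed frequency / background) with gap columns excluded (NaN);
    cells never observed are NaN as well. The center row is degenerate at Y.
    """

    k: int
    counts: pd.DataFrame
    frequencies: pd.DataFrame
    background: pd.Series
    log_odds: pd.DataFrame
    n_windows: int

    def log_odds_se(self) -> pd.DataFrame:
        """Approximate standard error of each log2-odds cell (delta method)."""
        nongap = self.counts[list(RESIDUES)]
        n = nongap.sum(axis=1).clip(lower=1)
        f = nongap.div(n, axis=0)
        se = np.sqrt((1.0 - f).div(n, axis=0) / f.clip(lower=1e-12)) / math.log(2)
        return se.where(f > 0)


def motif_matrix(
    windows: Sequence[str], background: pd.Series | Mapping[str, float]
) -> MotifMatrix:
    """Build the motif matrix from equal-length windows centered on Y."""
    if not windows:
        raise InputError("motif_matrix needs at least one window")
    width = len(windows[0])
    if width % 2 != 1 or any(len(w) != width for w in windows):
        raise InputError("windows must share one odd length")
    k = width // 2
    positions = list(range(-k, k + 1))
    alphabet = list(RESIDUES) + [GAP]
    counts = pd.DataFrame(0, index=positions, columns=alphabet, dtype=int)
    arr = np.array([list(w) for w in windows])
    for col, pos in enumerate(positions):
        vals, cnts = np.unique(arr[:, col], return_counts=True)
        for v, c in zip(vals, cnts):
            if v not in counts.columns:
                raise InputError(f"unexpected symbol {v!r} in window at {pos}")
            counts.loc[pos, v] = int(c)
    n = len(windows)
    frequencies = counts / n
    bg = pd.Series(background).reindex(list(RESIDUES))
    if bg.isna().any() or (bg <= 0).any():
        raise InputError("background must give a positive frequency for all residues")
    bg = bg / bg.sum()
    # odds are conditional on observing a residue (gap cells excluded)
    nongap = counts[list(RESIDUES)]
    cond = nongap.div(nongap.sum(axis=1).clip(lower=1), axis=0)
    with np.errstate(divide="ignore"):
        lo = np.log2(cond.where(cond > 0) / bg)
    log_odds = lo.reindex(columns=alphabet)  # gap column stays NaN
    return MotifMatrix(
        k=k,
        counts=counts,
        frequencies=frequencies,
        background=bg,
        log_odds=log_odds,
        n_windows=n,
    )
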