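"""Cosine spectral similarity between experimental and synthetic nitropeptide spectra.

The validation procedure: both spectra are normalized to relative intensity
(base peak = 100) and peaks at or below 2% of the base peak are discarded;
peaks are then matched one-to-one within a 0.01 Da tolerance into aligned
intensity vectors u and v (unmatched peaks pair with zero), and the score is

    cos(theta) = sum_i u_i v_i / sqrt(sum_i u_i^2 * sum_i v_i^2)

A pair is accepted when the score exceeds the 0.7 threshold. Intensities
enter the cosine untransformed; cosine is scale-invariant, so normalizing to
relative intensity changes nothing about the score while making the 2%
filter well defined across acquisitions.

Peak matching is greedy by ascending |delta m/z| under a one-to-one
constraint (ties broken by lower m/z), which is deterministic and agrees
with the exhaustive optimal assignment on all but rare ambiguous cases
(property-tested against a brute-force oracle).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .masses import (
    DEFAULT_MODIFICATIONS,
    InputError,
    Peptidoform,
    fragment_series,
)
from .spectra import Spectrum

__all__ = [
    "MatchParameters",
    "PeakAlignment",
    "SimilarityResult",
    "FragmentAnnotation",
    "MirrorData",
    "normalize_and_filter",
    "match_peaks",
    "cosine_similarity",
    "compare_spectra",
    "annotate_fragments",
    "mirror_data",
    "plot_mirror",
]


@dataclass(frozen=True)
class MatchParameters:
    """Tunables of the spectral comparison.

    match_tolerance : Da window for pairing peaks (default 0.01).
    base_peak_filter_fraction : peaks must exceed this fraction of the base
        peak to be kept (default 0.02, i.e. "over 2% of the base peak";
        strictly greater — a peak at exactly 2% is removed).
    similarity_threshold : acceptance cut on the cosine score (default 0.7;
        strictly greater passes).
    """

    match_tolerance: float = 0.01
    base_peak_filter_fraction: float = 0.02
    similarity_threshold: float = 0.7

    def __post_init__(self) -> None:
        if not self.match_tolerance > 0:
            raise InputError("match_tolerance must be > 0")
        if not 0 <= self.base_peak_filter_fraction < 1:
            raise InputError("base_peak_filter_fraction must be in [0, 1)")
        if not 0 <= self.similarity_threshold <= 1:
            raise InputError("similarity_threshold must be in [0, 1]")


@dataclass(frozen=True)
class PeakAlignment:
    """Aligned intensity vectors u, v plus the m/z bookkeeping behind them.

    Each alignment slot holds one matched pair (u_i > 0 and v_i > 0) or one
    unmatched peak from either spectrum (the other entry is 0; its m/z is
    NaN). Every input peak occupies exactly one slot.
    """

    u: np.ndarray
    v: np.ndarray
    mz_a: np.ndarray
    mz_b: np.ndarray

    @property
    def n(self) -> int:
        return int(self.u.size)

    @property
    def matched_count(self) -> int:
        return int(np.sum((self.u > 0) & (self.v > 0)))

    @property
    def matched(self) -> np.ndarray:
        return (self.u > 0) & (self.v > 0)


@dataclass(frozen=True)
class SimilarityResult:
    score: float
    alignment: PeakAlignment
    passed: bool


def normalize_and_filter(s: Spectrum, params: MatchParameters = MatchParameters()) -> Spectrum:
    """Rescale to relative intensity (base peak = 100) and apply the base-peak filter.

    Peaks strictly above ``100 * base_peak_filter_fraction`` relative
    intensity are kept; the base peak itself always survives.
    """
    if len(s) == 0 or s.base_peak_intensity <= 0:
        raise InputError(f"spectrum {s.identifier!r} has no positive-intensity peaks")
    rel = 100.0 * s.intensity / s.base_peak_intensity
    keep = rel > 100.0 * params.base_peak_filter_fraction
    keep |= rel == 100.0  # base peak always retained
    return s.replace(mz=s.mz[keep], intensity=rel[keep])


def match_peaks(
    a: Spectrum, b: Spectrum, params: MatchParameters = MatchParameters()
) -> PeakAlignment:
    """One-to-one peak matching within the m/z tolerance.

    Candidate pairs with |m/z_a - m/z_b| <= tolerance are accepted greedily in
    ascending |delta| order (ties: lower m/z first); each peak matches at most
    once. Unmatched peaks become (u_i, 0) or (0, v_i) slots.
    """
    if len(a) == 0 and len(b) == 0:
        raise InputError("cannot align two empty spectra")
    tol = params.match_tolerance
    candidates: list[tuple[float, float, int, int]] = []
    # b-window per a-peak via searchsorted keeps this near-linear
    lo = np.searchsorted(b.mz, a.mz - tol, side="left")
    hi = np.searchsorted(b.mz, a.mz + tol, side="right")
    for i in range(len(a)):
        for j in range(int(lo[i]), int(hi[i])):
            d = abs(a.mz[i] - b.mz[j])
            if d <= tol:
                candidates.append((d, min(a.mz[i], b.mz[j]), i, j))
    candidates.sort()

    a_used = np.zeros(len(a), dtype=bool)
    b_used = np.zeros(len(b), dtype=bool)
    pairs: list[tuple[int, int]] = []
    for _, _, i, j in candidates:
        if not a_used[i] and not b_used[j]:
            a_used[i] = b_used[j] = True
            pairs.append((i, j))

    slots: list[tuple[float, float, float, float, float]] = []  # (sort key, u, v, mza, mzb)
    for i, j in pairs:
        slots.append((a.mz[i], a.intensity[i], b.intensity[j], a.mz[i], b.mz[j]))
    for i in np.nonzero(~a_used)[0]:
        slots.append((a.mz[i], a.intensity[i], 0.0, a.mz[i], np.nan))
    for j in np.nonzero(~b_used)[0]:
        slots.append((b.mz[j], 0.0, b.intensity[j], np.nan, b.mz[j]))
    slots.sort(key=lambda t: t[0])

    arr = np.array([s[1:] for s in slots], dtype=float).reshape(-1, 4)
    return PeakAlignment(u=arr[:, 0], v=arr[:, 1], mz_a=arr[:, 2], mz_b=arr[:, 3])


def cosine_similarity(alignment: PeakAlignment) -> float:
    """The cosine of the aligned intensity vectors; 0.0 when nothing matched."""
    u, v = alignment.u, alignment.v
    nu = float(np.sqrt(np.sum(u * u)))
    nv = float(np.sqrt(np.sum(v * v)))
    if nu == 0.0 or nv == 0.0:
        raise InputError("cosine undefined: one aligned vector is all-zero")
    if alignment.matched_count == 0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


def compare_spectra(
    a: Spectrum, b: Spectrum, params: MatchParameters = MatchParameters()
) -> SimilarityResult:
    """normalize/filter -> match -> cosine; ``passed`` is score > threshold."""
    an = normalize_and_filter(a, params)
    bn = normalize_and_filter(b, params)
    alignment = match_peaks(an, bn, params)
    score = cosine_similarity(alignment)
    return SimilarityResult(
        score=score, alignment=alignment, passed=score > params.similarity_threshold
    )


@dataclass(frozen=True)
class FragmentAnnotation:
    """Per-peak optional b/y ion labels for one spectrum against one peptidoform."""

    labels: tuple[tuple[str, int, int] | None, ...]  # (series, ordinal, charge)
    errors_da: tuple[float, ...]  # NaN where unlabeled

    @property
    def n_annotated(self) -> int:
        return sum(1 for x in self.labels if x is not None)

    def fraction_annotated(self) -> float:
        return self.n_annotated / len(self.labels) if self.labels else 0.0


def annotate_fragments(
    s: Spectrum,
    p: Peptidoform,
    annotation_tolerance: float = 0.01,
    max_fragment_charge: int = 2,
    mods=DEFAULT_MODIFICATIONS,
) -> FragmentAnnotation:
    """Label each peak with its closest theoretical b/y ion within tolerance.

    Ties are broken by smaller |delta m/z|, then lower charge, then y over b.
    """
    ions = fragment_series(p, max_fragment_charge=max_fragment_charge, mods=mods)
    labels: list[tuple[str, int, int] | None] = []
    errors: list[float] = []
    for mz in s.mz:
        best = None
        best_key = None
        for ion in ions:
            d = abs(mz - ion.mz)
            if d <= annotation_tolerance:
                key = (d, ion.charge, 0 if ion.series == "y" else 1)
                if best_key is None or key < best_key:
                    best_key = key
                    best = ion
        if best is None:
            labels.append(None)
            errors.append(float("nan"))
        else:
            labels.append((best.series, best.ordinal, best.charge))
            errors.append(float(mz - best.mz))
    return FragmentAnnotation(labels=tuple(labels), errors_da=tuple(errors))


@dataclass(frozen=True)
class MirrorData:
    """Plot-ready mirror representation: experimental up, synthetic mirrored down."""

    top_mz: np.ndarray
    top_intensity: np.ndarray
    top_matched: np.ndarray
    bottom_mz: np.ndarray
    bottom_intensity: np.ndarray  # negated relative intensities
    bottom_matched: np.ndarray
    score: float


def mirror_data(a: Spectrum, b: Spectrum, result: SimilarityResult) -> MirrorData:
    """Assemble mirror-plot data from a comparison (a on top, b negated below)."""
    al = result.alignment
    m = al.matched
    matched_a = set(al.mz_a[m].tolist())
    matched_b = set(al.mz_b[m].tolist())
    top = al.u > 0
    bot = al.v > 0
    return MirrorData(
        top_mz=al.mz_a[top],
        top_intensity=al.u[top],
        top_matched=np.array([x in matched_a for x in al.mz_a[top]]),
        bottom_mz=al.mz_b[bot],
        bottom_intensity=-al.v[bot],
        bottom_matched=np.array([x in matched_b for x in al.mz_b[bot]]),
        score=result.score,
    )


def plot_mirror(data: MirrorData, title: str = "", path=None):
    """Render a mirror plot (matched peaks highlighted); save if ``path`` given."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4.5))
    for mzs, ints, matched in (
        (data.top_mz, data.top_intensity, data.top_matched),
        (data.bottom_mz, data.bottom_intensity, data.bottom_matched),
    ):
        if mzs.size:
            colors = np.where(matched, "#c0392b", "#7f8c8d")
            ax.vlines(mzs, 0, ints, colors=colors, linewidth=1.0)
    ax.axhline(0, color="black", linewidth=0.8)
    ax.set_xlabel("m/z")
    ax.set_ylabel("relative intensity")
    ax.set_ylim(-110, 110)
    label = f"cosine = {data.score:.3f}"
    ax.set_title(f"{title}  ({label})" if title else label)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
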