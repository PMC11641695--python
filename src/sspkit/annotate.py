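"""Whole-protein annotation by sliding windows, plus Q3/Q8 scoring.

Every subsequence of length 4-30 is predicted independently; each residue
inherits, per class, the maximal Pa - Pi over the windows covering it, and
is assigned the argmax class (deterministic priority order on ties).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Protocol, Sequence

from .sspr import SSP_CLASSES

__all__ = [
    "Window",
    "ResidueAnnotation",
    "QResult",
    "WindowScorer",
    "DEFAULT_8_TO_3",
    "CLASS_PRIORITY",
    "enumerate_windows",
    "annotate_protein",
    "annotations_to_codes",
    "map_8_to_3",
    "q_score",
    "smooth_codes",
]

#: Default reduction of the eight structure codes (plus B) to helix/strand/coil.
DEFAULT_8_TO_3: dict[str, str] = {
    "H": "H",
    "G": "H",
    "I": "H",
    "E": "E",
    "B": "E",
    "C": "C",
    "T": "C",
    "S": "C",
    "P": "C",
}

#: Tie-break order for the per-residue argmax (most to least frequent class).
CLASS_PRIORITY: tuple[str, ...] = ("H", "E", "C", "T", "S", "G", "P", "I")


class WindowScorer(Protocol):
    """Anything that maps a subsequence to per-class Pa - Pi deltas."""

    def window_deltas(self, sequence: str) -> Mapping[str, float]: ...


@dataclass(frozen=True)
class Window:
    start: int  # 1-based
    length: int

    @property
    def end(self) -> int:  # 1-based inclusive
        return self.start + self.length - 1

    def slice(self, sequence: str) -> str:
        return sequence[self.start - 1 : self.end]


@dataclass
class ResidueAnnotation:
    position: int  # 1-based
    deltas: dict[str, float]  # best Pa - Pi per class
    best_class: str
    best_windows: dict[str, Window]  # per class, the window achieving the max

    @property
    def best_delta(self) -> float:
        return self.deltas[self.best_class]


@dataclass(frozen=True)
class QResult:
    q: float  # percentage in [0, 100]
    n: int
    matches: int
    confusion: dict[tuple[str, str], int]  # (true, predicted) -> count


def enumerate_windows(sequence: str, wmin: int = 4, wmax: int = 30) -> list[Window]:
    """All (start, length) windows with wmin <= length <= min(wmax, L),
    ordered by start then length."""
    if wmin < 1 or wmax < wmin:
        raise ValueError(f"invalid window bounds [{wmin}, {wmax}]")
    n = len(sequence)
    if n < wmin:
        import warnings

        warnings.warn(f"sequence of length {n} is shorter than wmin={wmin}", stacklevel=2)
        return []
    return [
        Window(start, length)
        for start in range(1, n - wmin + 2)
        for length in range(wmin, min(wmax, n - start + 1) + 1)
    ]


def annotate_protein(
    model: WindowScorer,
    sequence: str,
    wmin: int = 4,
    wmax: int = 30,
) -> list[ResidueAnnotation]:
    """Annotate every residue with its per-class max-over-windows delta.

    ``model`` needs only a ``window_deltas`` method, so trained models and
    test stubs are interchangeable.
    """
    n = len(sequence)
    if n < wmin:
        raise ValueError(
            f"sequence of length {n} is below the minimum predictable "
            f"segment length of {wmin} residues"
        )
    best: list[dict[str, float]] = [{} for _ in range(n)]
    best_win: list[dict[str, Window]] = [{} for _ in range(n)]
    for window in enumerate_windows(sequence, wmin, wmax):
        deltas = model.window_deltas(window.slice(sequence))
        for pos in range(window.start - 1, window.end):
            for cls, delta in deltas.items():
                if cls not in best[pos] or delta > best[pos][cls]:
                    best[pos][cls] = delta
                    best_win[pos][cls] = window
    annotations = []
    for pos in range(n):
        deltas = best[pos]
        ranked = [c for c in CLASS_PRIORITY if c in deltas]
        ranked += [c for c in deltas if c not in CLASS_PRIORITY]
        best_class = max(ranked, key=lambda c: deltas[c]) if ranked else ""
        annotations.append(
            ResidueAnnotation(pos + 1, deltas, best_class, best_win[pos])
        )
    return annotations


def annotations_to_codes(annotations: Sequence[ResidueAnnotation]) -> str:
    return "".join(a.best_class for a in annotations)


def map_8_to_3(codes: str, mapping: Mapping[str, str] | None = None) -> str:
    """Reduce an 8-state code string to 3 states (helix/strand/coil)."""
    table = DEFAULT_8_TO_3 if mapping is None else mapping
    out = []
    for ch in codes:
        if ch not in table:
            raise ValueError(f"unknown structure code {ch!r}")
        out.append(table[ch])
    return "".join(out)


def q_score(
    true_codes: str,
    pred_codes: str,
    states: int = 8,
    mapping: Mapping[str, str] | None = None,
) -> QResult:
    """Per-residue accuracy Q = 100 * (1/N) * sum of match indicators.

    With ``states=3`` both strings are reduced to helix/strand/coil first.
    """
    if len(true_codes) != len(pred_codes):
        raise ValueError(
            f"length mismatch: {len(true_codes)} true vs {len(pred_codes)} predicted"
        )
    if len(true_codes) == 0:
        raise ValueError("empty code strings")
    if states == 3:
        true_codes = map_8_to_3(true_codes, mapping)
        pred_codes = map_8_to_3(pred_codes, mapping)
    elif states != 8:
        raise ValueError(f"states must be 3 or 8, got {states}")
    confusion: dict[tuple[str, str], int] = {}
    matches = 0
    for t, p in zip(true_codes, pred_codes):
        confusion[(t, p)] = confusion.get((t, p), 0) + 1
        if t == p:
            matches += 1
    n = len(true_codes)
    return QResult(100.0 * matches / n, n, matches, confusion)


def smooth_codes(codes: str, min_run: int = 4, fill: str = "C") -> str:
    """Optional post-pass: replace predicted runs shorter than ``min_run``
    with ``fill`` (coil).  Runs already equal to ``fill`` are left alone."""
    out = list(codes)
    i, n = 0, len(codes)
    while i < n:
        j = i
        while j < n and codes[j] == codes[i]:
            j += 1
        if j - i < min_run and codes[i] != fill:
            out[i:j] = fill * (j - i)
        i = j
    return "".join(out)
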