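"""Courtship summaries over a labeled frame sequence.

Total courtship time sums the four active elements (orientation, tapping,
singing, attempted copulation); copulation itself and "none" frames do not
count.  Element proportions divide each element's time by the observation
window, which may be the full recording, the stretch up to copulation
onset, or a fixed duration (the mated/unmated convention — the comparison
duration is data-derived and therefore a parameter).  The transition matrix
counts changes from element A to element B (self-transitions are not
changes) and row-normalizes them into conditional probabilities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import ATTEMPTED, COPULATION, COURTSHIP_ELEMENTS, NONE


@dataclass
class Ethogram:
    """A per-frame label sequence with its timebase and analysis window."""

    labels: list
    fps: float = 24.0
    window: tuple[int, int] | None = None  # (start, stop) frame, stop exclusive

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.window is None:
            self.window = (0, len(self.labels))
        lo, hi = self.window
        if not (0 <= lo <= hi <= len(self.labels)):
            raise ValueError(f"window {self.window} outside sequence bounds")

    def window_labels(self) -> list:
        lo, hi = self.window
        return list(self.labels[lo:hi])

    def copulation_onset(self) -> int | None:
        """First copulation frame in the full sequence, or None."""
        for i, lab in enumerate(self.labels):
            if lab == COPULATION:
                return i
        return None

    def with_window(self, mode: str = "full",
                    seconds: float | None = None) -> "Ethogram":
        """Re-window: 'full', 'to-copulation', or 'seconds' (fixed duration)."""
        if mode == "full":
            win = (0, len(self.labels))
        elif mode == "to-copulation":
            onset = self.copulation_onset()
            win = (0, onset if onset is not None else len(self.labels))
        elif mode == "seconds":
            if seconds is None:
                raise ValueError("mode 'seconds' needs a duration")
            win = (0, min(len(self.labels), int(round(seconds * self.fps))))
        else:
            raise ValueError(f"unknown window mode {mode!r}")
        return Ethogram(labels=self.labels, fps=self.fps, window=win)


@dataclass
class TransitionMatrix:
    elements: tuple
    counts: np.ndarray          # integer element x element grid
    probabilities: np.ndarray   # row-normalized; NaN rows where no change left A
    undefined_rows: list = field(default_factory=list)

    def to_frame(self, kind: str = "probabilities") -> pd.DataFrame:
        data = self.probabilities if kind == "probabilities" else self.counts
        return pd.DataFrame(data, index=list(self.elements),
                            columns=list(self.elements))


def total_courtship_time(e: Ethogram) -> float:
    """Seconds of active courtship (the four elements) inside the window."""
    labs = e.window_labels()
    n = sum(1 for lab in labs if lab in COURTSHIP_ELEMENTS)
    return n / e.fps


def element_proportions(e: Ethogram, truncate_at_copulation: bool = False) -> dict:
    """Per-element time fraction of the observation window.

    With ``truncate_at_copulation`` the window is cut at the first
    copulation frame before normalizing (the mated-male convention).
    """
    if truncate_at_copulation:
        onset = e.copulation_onset()
        if onset is not None:
            lo, hi = e.window
            e = Ethogram(labels=e.labels, fps=e.fps, window=(lo, min(hi, onset)))
    labs = e.window_labels()
    if len(labs) == 0:
        raise ValueError("zero-length observation window")
    out = {}
    for el in COURTSHIP_ELEMENTS:
        out[el] = sum(1 for lab in labs if lab == el) / len(labs)
    out[COPULATION] = sum(1 for lab in labs if lab == COPULATION) / len(labs)
    out[NONE] = sum(1 for lab in labs if lab == NONE) / len(labs)
    return out


def transition_matrix(e: Ethogram, include_none: bool = False,
                      bridge_none: bool = False) -> TransitionMatrix:
    """Counts and probabilities of changes between certified labels.

    A change is a consecutive pair A -> B with A != B.  ``none`` may either
    participate as a state (``include_none``), break a chain (default), or
    be skipped over so A,none,B counts as A -> B (``bridge_none``).
    """
    elements = tuple(list(COURTSHIP_ELEMENTS) + [COPULATION] +
                     ([NONE] if include_none else []))
    idx = {el: i for i, el in enumerate(elements)}
    k = len(elements)
    counts = np.zeros((k, k), int)
    labs = e.window_labels()
    if not include_none and bridge_none:
        labs = [lab for lab in labs if lab != NONE]
    prev = None
    for lab in labs:
        if lab not in idx:
            prev = None  # a non-state label breaks the chain
            continue
        if prev is not None and lab != prev:
            counts[idx[prev], idx[lab]] += 1
        prev = lab
    row_sums = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = counts / row_sums[:, None]
    undefined = [elements[i] for i in range(k) if row_sums[i] == 0]
    return TransitionMatrix(elements=elements, counts=counts,
                            probabilities=probs, undefined_rows=undefined)


def courtship_pattern_summary(proportions: dict, matrix: TransitionMatrix,
                              total_courtship_s: float | None = None,
                              diagram_path=None) -> dict:
    """Machine-readable courtship-pattern report, optionally with a diagram.

    Nodes are the behavioral elements sized by their time proportion;
    arrows carry the transition probabilities.
    """
    report = {
        "proportions": {k: float(v) for k, v in proportions.items()},
        "transition_elements": list(matrix.elements),
        "transition_counts": matrix.counts.tolist(),
        "transition_probabilities": [
            [None if not np.isfinite(v) else float(v) for v in row]
            for row in matrix.probabilities
        ],
        "undefined_rows": list(matrix.undefined_rows),
    }
    if total_courtship_s is not None:
        report["total_courtship_s"] = float(total_courtship_s)
    if diagram_path is not None:
        _draw_pattern_diagram(report, diagram_path)
        report["diagram"] = str(diagram_path)
    return report


def _draw_pattern_diagram(report: dict, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    elements = [el for el in report["transition_elements"] if el != NONE]
    props = report["proportions"]
    k = len(elements)
    angles = np.linspace(0, 2 * np.pi, k, endpoint=False)
    xy = np.column_stack([np.cos(angles), np.sin(angles)])
    fig, ax = plt.subplots(figsize=(5, 5))
    full = report["transition_elements"]
    probs = report["transition_probabilities"]
    for i, a in enumerate(elements):
        for j, b in enumerate(elements):
            if i == j:
                continue
            pij = probs[full.index(a)][full.index(b)]
            if pij:
                ax.annotate("", xy=xy[j], xytext=xy[i],
                            arrowprops=dict(width=0.3 + 4 * pij,
                                            headwidth=4 + 8 * pij,
                                            color="tab:gray", alpha=0.7))
    for i, el in enumerate(elements):
        size = 300 + 4000 * props.get(el, 0.0)
        ax.scatter(*xy[i], s=size, zorder=3)
        ax.annotate(el, xy[i], ha="center", va="center", zorder=4, fontsize=8)
    ax.set_xlim(-1.5, 1.5)
    ax.set_ylim(-1.5, 1.5)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_summary_json(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1)


def read_summary_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
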