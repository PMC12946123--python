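"""Published benchmark constants for worked-example metric computations.

These are reported results from the 28-species medicinal-herb FSCIL
benchmark (16 base classes, 4 incremental 3-way 5-shot sessions): per-class
precision/recall/F1 rows and session-level harmonic-mean (HM) columns for
the frequency-aware method and the baselines it was compared against.
They serve as *inputs* to worked examples — recomputing an F1 from its
printed precision/recall, or an improvement delta from two printed HMs —
and as the stored reference for improvement reporting.  Nothing in the
training pipeline reads them.

One reported per-class row (class "O") contains an impossible recall value
(636.0) and is excluded.
"""

from __future__ import annotations

__all__ = [
    "PER_CLASS_PR",
    "METHOD_HM",
    "BASE_SPLIT_HM",
    "CROP_SIZE_HM",
    "REFERENCE_HM",
]

#: class -> (precision %, recall %, reported F1 %)
PER_CLASS_PR: dict[str, tuple[float, float, float]] = {
    "A": (100.0, 100.0, 100.0),
    "B": (82.4, 82.4, 82.4),
    "C": (100.0, 99.6, 99.8),
    "D": (90.2, 96.0, 93.0),
    "Q": (57.9, 62.0, 59.9),
    "R": (45.8, 84.5, 59.4),
    "S": (88.9, 76.0, 81.9),
    "T": (30.3, 62.0, 40.7),
}

#: method -> reported harmonic mean % on the 28-species benchmark
METHOD_HM: dict[str, float] = {
    "icarl": 58.774,
    "fsll": 75.023,
    "c_fscil": 78.411,
    "fact": 79.284,
    "savc": 84.328,
    "wang": 83.101,
    "fgde": 86.599,
}

#: base-session size ablation: base classes -> HM %
BASE_SPLIT_HM: dict[int, float] = {12: 74.092, 16: 86.599}

#: crop-size ablation: crop pixels -> HM %
CROP_SIZE_HM: dict[int, float] = {128: 86.599, 96: 78.690, 64: 78.977, 32: 74.622}

#: the frequency-aware method's own reported HM
REFERENCE_HM: float = METHOD_HM["fgde"]
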