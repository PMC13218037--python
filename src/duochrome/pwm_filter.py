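"""Position-weight-matrix likelihood-ratio filtering of artifact-prone calls.

For each collapsed substitution class, an 8-base window (4 bases either side
of the variant, variant base excluded, pyrimidine frame) is collected around
every training call on each platform, and a PWM with Laplace pseudocounts is
built per platform. A candidate call is scored by the log-likelihood ratio
of its window under the two-color-platform PWM versus the four-color-platform
PWM; because the PWM factorizes over positions, the null distribution of this
score for a window drawn from the four-color PWM is an exact convolution of
eight 4-outcome distributions. Calls whose score is significantly large under
that null (one-sided, p < alpha) are flagged as artifacts and removed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ReferenceGenome, VariantCall
from .sequence import BASES, BASE_INDEX, SBS_CLASSES, collapse_sbs
from .context_spectra import ContextUndefined, _oriented_flanks

log = logging.getLogger(__name__)

DEFAULT_FLANK = 4
DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_ALPHA = 0.05
_MERGE_TOL = 1e-12


@dataclass
class PWM:
    """Column-stochastic base probabilities over the flanking offsets.

    ``probs`` has shape (2*flank, 4) in base order A, C, G, T; row order is
    offsets -flank..-1, +1..+flank in the pyrimidine frame.
    """

    probs: np.ndarray
    pseudocount: float
    n_windows: int
    sbs_class: str | None = None
    platform: str = ""

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        sums = self.probs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1")
        if np.any(self.probs <= 0):
            raise ValueError("PWM probabilities must be strictly positive")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def offsets(self) -> list[int]:
        flank = self.width // 2
        return [o for o in range(-flank, flank + 1) if o != 0]

    def log_likelihood(self, window: str) -> float:
        idx = [BASE_INDEX[b] for b in window]
        return float(np.log(self.probs[np.arange(self.width), idx]).sum())

    def to_dict(self) -> dict:
        return {
            "probs": self.probs.tolist(),
            "pseudocount": self.pseudocount,
            "n_windows": self.n_windows,
            "sbs_class": self.sbs_class,
            "platform": self.platform,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PWM":
        return cls(
            probs=np.asarray(d["probs"]),
            pseudocount=d["pseudocount"],
            n_windows=d["n_windows"],
            sbs_class=d.get("sbs_class"),
            platform=d.get("platform", ""),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "PWM":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def extract_window(
    genome: ReferenceGenome, call: VariantCall, flank: int = DEFAULT_FLANK
) -> str:
    """2*flank-base window around a call, variant base excluded, reverse-
    complemented into the pyrimidine frame for purine-referenced calls.
    Raises ContextUndefined on N bases or a contig edge."""
    left, right = _oriented_flanks(genome, call, flank)
    return left + right


def build_pwm(
    windows: list[str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    sbs_class: str | None = None,
    platform: str = "",
) -> PWM:
    """Laplace-smoothed PWM: p[j][b] = (count_j(b) + k) / (n + 4k)."""
    if not windows:
        raise ValueError(
            "no training windows; provide a larger callset or pool classes"
        )
    width = len(windows[0])
    counts = np.zeros((width, 4), dtype=float)
    for w in windows:
        if len(w) != width:
            raise ValueError("training windows must share one length")
        for j, b in enumerate(w):
            counts[j, BASE_INDEX[b]] += 1
    probs = (counts + pseudocount) / (len(windows) + 4 * pseudocount)
    return PWM(
        probs=probs,
        pseudocount=pseudocount,
        n_windows=len(windows),
        sbs_class=sbs_class,
        platform=platform,
    )


def loglr(window: str, pwm_nova: PWM, pwm_hiseq: PWM) -> float:
    """Natural-log likelihood ratio of the window: two-color over four-color."""
    return pwm_nova.log_likelihood(window) - pwm_hiseq.log_likelihood(window)


@dataclass
class NullDistribution:
    """Exact distribution of the loglr statistic for windows drawn
    position-independently from the four-color (denominator) PWM."""

    values: np.ndarray  # sorted ascending
    probs: np.ndarray

    def __post_init__(self):
        if not np.isclose(self.probs.sum(), 1.0, atol=1e-9):
            raise ValueError("null atoms must sum to 1")

    def sf(self, x: float) -> float:
        """P(loglr >= x), the tie-inclusive upper tail."""
        return float(self.probs[self.values >= x - 1e-9].sum())


def null_distribution(pwm_nova: PWM, pwm_hiseq: PWM) -> NullDistribution:
    """Convolve the per-position 4-outcome log-ratio distributions exactly.

    Atoms within 1e-12 of each other are merged, so the result stays well
    below the worst-case 4^width atom count.
    """
    if pwm_nova.width != pwm_hiseq.width:
        raise ValueError("PWMs must share width/frame")
    step_vals = np.log(pwm_nova.probs / pwm_hiseq.probs)
    vals = np.array([0.0])
    probs = np.array([1.0])
    for j in range(pwm_nova.width):
        vals = (vals[:, None] + step_vals[j][None, :]).ravel()
        probs = (probs[:, None] * pwm_hiseq.probs[j][None, :]).ravel()
        order = np.argsort(vals, kind="stable")
        vals, probs = vals[order], probs[order]
        # merge runs of (near-)equal atoms
        boundary = np.empty(len(vals), dtype=bool)
        boundary[0] = True
        boundary[1:] = np.diff(vals) > _MERGE_TOL
        group = np.cumsum(boundary) - 1
        vals = vals[boundary]
        probs = np.bincount(group, weights=probs)
    return NullDistribution(values=vals, probs=probs)


@dataclass
class LRResult:
    call: VariantCall
    window: str | None
    loglr: float | None
    p_value: float | None
    artifact: bool
    status: str = "evaluated"  # or "unevaluated"


def classify(
    call: VariantCall,
    genome: ReferenceGenome,
    pwm_nova: PWM,
    pwm_hiseq: PWM,
    null: NullDistribution,
    alpha: float = DEFAULT_ALPHA,
    flank: int = DEFAULT_FLANK,
) -> LRResult:
    """Score one call; artifact iff P_null(loglr >= observed) < alpha.

    Calls whose window cannot be extracted pass through unflagged with
    status 'unevaluated'.
    """
    try:
        window = extract_window(genome, call, flank)
    except ContextUndefined:
        return LRResult(call, None, None, None, artifact=False, status="unevaluated")
    score = loglr(window, pwm_nova, pwm_hiseq)
    p = null.sf(score)
    return LRResult(call, window, score, p, artifact=p < alpha)


@dataclass
class CorrectionResult:
    kept: list[VariantCall]
    flagged: list[VariantCall]
    results: list[LRResult]
    summary: pd.DataFrame  # per-class before/after counts and fold change
    pwms: dict[str, tuple[PWM, PWM]] = field(default_factory=dict)


def correct_callset(
    calls: list[VariantCall],
    genome: ReferenceGenome,
    training_nova: list[VariantCall],
    training_hiseq: list[VariantCall],
    alpha: float = DEFAULT_ALPHA,
    classes: set[str] | None = None,
    flank: int = DEFAULT_FLANK,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> CorrectionResult:
    """Build per-class per-platform PWMs from the training callsets, score
    every call of a requested class, and split the callset into kept and
    flagged calls with a per-class summary.

    Classes with no usable training windows on either platform are skipped
    with a warning; their calls (and calls of classes outside ``classes``)
    pass through unflagged. Training and test callsets may coincide.
    """
    classes = set(classes) if classes is not None else set(SBS_CLASSES)

    def windows_by_class(training: list[VariantCall]) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {c: [] for c in SBS_CLASSES}
        for call in training:
            try:
                out[collapse_sbs(call.ref, call.alt)].append(
                    extract_window(genome, call, flank)
                )
            except ContextUndefined:
                continue
        return out

    win_nova = windows_by_class(training_nova)
    win_hiseq = windows_by_class(training_hiseq)
    machinery: dict[str, tuple[PWM, PWM, NullDistribution]] = {}
    pwms: dict[str, tuple[PWM, PWM]] = {}
    for cls in sorted(classes):
        if not win_nova[cls] or not win_hiseq[cls]:
            log.warning(
                "class %s: empty training set on one platform; calls pass through",
                cls,
            )
            continue
        pn = build_pwm(win_nova[cls], pseudocount, cls, platform="nova")
        ph = build_pwm(win_hiseq[cls], pseudocount, cls, platform="hiseq")
        machinery[cls] = (pn, ph, null_distribution(pn, ph))
        pwms[cls] = (pn, ph)

    kept, flagged, results = [], [], []
    for call in calls:
        cls = collapse_sbs(call.ref, call.alt)
        if cls not in machinery:
            kept.append(call)
            continue
        pn, ph, null = machinery[cls]
        res = classify(call, genome, pn, ph, null, alpha=alpha, flank=flank)
        results.append(res)
        (flagged if res.artifact else kept).append(call)

    rows = []
    for cls in SBS_CLASSES:
        before = sum(1 for c in calls if collapse_sbs(c.ref, c.alt) == cls)
        removed = sum(1 for c in flagged if collapse_sbs(c.ref, c.alt) == cls)
        after = before - removed
        rows.append(
            {
                "sbs_class": cls,
                "n_before": before,
                "n_flagged": removed,
                "n_after": after,
                "fold_change": before / after if after else np.inf,
            }
        )
    summary = pd.DataFrame(rows).set_index("sbs_class")
    return CorrectionResult(
        kept=kept, flagged=flagged, results=results, summary=summary, pwms=pwms
    )
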