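"""Clinical posture classification from per-sample angles.

Thresholds follow the screening criteria in common clinical use: forward
head posture (FHP) when the craniovertebral angle falls below 48 degrees,
a shoulder angle above 54 degrees as a corroborating sign of compensatory
shoulder protraction, and hyperkyphosis when the kyphosis angle exceeds
40 degrees.  All comparisons are strict, so a sample sitting exactly on a
threshold classifies as non-pathological.

The CA is the deciding FHP criterion; the SA exceedance is carried along
as a flag rather than required, because shoulder adaptation is a secondary
sign and may lag the head displacement.  A strict-conjunction mode
(``require_sa=True``) is available for users who want both.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

from .errors import EmptySessionError
from .session import SessionSeries

__all__ = [
    "PostureCriteria",
    "HeadLabel",
    "SpineLabel",
    "PostureLabel",
    "SessionSummary",
    "classify_sample",
    "summarize_session",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PostureCriteria:
    """Clinical thresholds, degrees; defaults are the published cutoffs."""

    ca_fhp_below: float = 48.0
    sa_fhp_above: float = 54.0
    ka_kyphosis_above: float = 40.0
    require_sa: bool = False  # strict conjunction: FHP needs CA and SA criteria

    def __post_init__(self) -> None:
        if min(self.ca_fhp_below, self.sa_fhp_above, self.ka_kyphosis_above) <= 0:
            raise ValueError("posture thresholds must be positive")


class HeadLabel(str, enum.Enum):
    FHP = "FHP"
    NHP = "NHP"
    INDETERMINATE = "indeterminate"


class SpineLabel(str, enum.Enum):
    KYPHOTIC = "kyphotic"
    NORMAL = "normal"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class PostureLabel:
    """Head and spine labels for one sample.

    ``sa_exceeds`` records whether the shoulder angle crossed its
    threshold (None when SA was not measured); in the default mode it is
    informational only.
    """

    head: HeadLabel
    spine: SpineLabel
    sa_exceeds: bool | None = None


def classify_sample(sample, criteria: PostureCriteria | None = None) -> PostureLabel:
    """Label one sample; accepts any object carrying angle attributes.

    Looks for ``ca_deg``/``sa_deg`` (sagittal tracking samples) and
    ``ka_deg`` (kyphosis samples); whichever angles are absent leave the
    corresponding label indeterminate.
    """
    criteria = criteria or PostureCriteria()
    ca = getattr(sample, "ca_deg", None)
    sa = getattr(sample, "sa_deg", None)
    ka = getattr(sample, "ka_deg", None)

    sa_exceeds = None if sa is None else sa > criteria.sa_fhp_above

    if ca is None:
        head = HeadLabel.INDETERMINATE
    else:
        is_fhp = ca < criteria.ca_fhp_below
        if criteria.require_sa:
            if sa is None:
                head = HeadLabel.INDETERMINATE
            else:
                head = HeadLabel.FHP if (is_fhp and sa_exceeds) else HeadLabel.NHP
        else:
            head = HeadLabel.FHP if is_fhp else HeadLabel.NHP

    if ka is None:
        spine = SpineLabel.INDETERMINATE
    else:
        spine = SpineLabel.KYPHOTIC if ka > criteria.ka_kyphosis_above else SpineLabel.NORMAL

    return PostureLabel(head=head, spine=spine, sa_exceeds=sa_exceeds)


@dataclass
class SessionSummary:
    """Label counts and fractions over one session."""

    n_samples: int
    head_counts: dict[str, int] = field(default_factory=dict)
    spine_counts: dict[str, int] = field(default_factory=dict)
    fhp_fraction: float | None = None       # over head-determinate samples
    kyphotic_fraction: float | None = None  # over spine-determinate samples
    sa_exceed_fraction: float | None = None
    longest_fhp_run_s: float = 0.0

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "head_counts": self.head_counts,
            "spine_counts": self.spine_counts,
            "fhp_fraction": self.fhp_fraction,
            "kyphotic_fraction": self.kyphotic_fraction,
            "sa_exceed_fraction": self.sa_exceed_fraction,
            "longest_fhp_run_s": self.longest_fhp_run_s,
        }


def summarize_session(
    series: SessionSeries,
    criteria: PostureCriteria | None = None,
) -> SessionSummary:
    """Classify every sample and aggregate label statistics.

    Fractions are taken over determinate samples only; when a whole
    channel is indeterminate its fraction is None but counts are still
    reported.  The longest consecutive FHP run is measured in samples and
    reported in seconds (1 Hz sessions: one sample = one second).
    """
    criteria = criteria or PostureCriteria()
    if len(series) == 0:
        raise EmptySessionError("cannot summarize an empty session")

    labels = [classify_sample(s, criteria) for s in series]
    head_counts = {label.value: 0 for label in HeadLabel}
    spine_counts = {label.value: 0 for label in SpineLabel}
    sa_known = sa_exceed = 0
    longest_run = run = 0
    for lab in labels:
        head_counts[lab.head.value] += 1
        spine_counts[lab.spine.value] += 1
        if lab.sa_exceeds is not None:
            sa_known += 1
            sa_exceed += int(lab.sa_exceeds)
        run = run + 1 if lab.head is HeadLabel.FHP else 0
        longest_run = max(longest_run, run)

    n_head = head_counts[HeadLabel.FHP.value] + head_counts[HeadLabel.NHP.value]
    n_spine = spine_counts[SpineLabel.KYPHOTIC.value] + spine_counts[SpineLabel.NORMAL.value]
    return SessionSummary(
        n_samples=len(series),
        head_counts=head_counts,
        spine_counts=spine_counts,
        fhp_fraction=head_counts[HeadLabel.FHP.value] / n_head if n_head else None,
        kyphotic_fraction=(
            spine_counts[SpineLabel.KYPHOTIC.value] / n_spine if n_spine else None
        ),
        sa_exceed_fraction=sa_exceed / sa_known if sa_known else None,
        longest_fhp_run_s=float(longest_run),
    )
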