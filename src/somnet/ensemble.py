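"""Majority-vote ensemble of local models.

Each member is a model trained on one site ("local expert"); an ensemble
predicting dataset k must exclude the member trained on k so the target
stays external to every voter.  Votes are hard labels; ties are broken by
the largest summed posterior over the tied stages, then by the fixed stage
order W < N1 < N2 < N3 < R.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np

from .model import RecordingPatterns, SleepStager
from .psg_io import AASM_STAGES, Hypnogram, ValidationError


@dataclasses.dataclass
class EnsembleSpec:
    """Members as (model, origin-dataset id) pairs."""

    members: list[tuple[SleepStager, str]]
    excluded_origin: Optional[str] = None

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValidationError("an ensemble needs at least 2 members")
        if self.excluded_origin is not None:
            bad = [o for _, o in self.members if o == self.excluded_origin]
            if bad:
                raise ValidationError(
                    f"member with origin {self.excluded_origin!r} must be excluded"
                )
        variants = {m.cfg.name for m, _ in self.members}
        if len(variants) != 1:
            raise ValidationError(
                f"ensemble members must share one variant, got {sorted(variants)}"
            )


def majority_vote(
    stage_votes: Sequence[str], posteriors: Optional[Sequence[np.ndarray]] = None
) -> str:
    """Stage with the highest vote count.

    Ties are resolved by the highest posterior mass summed over the voters,
    restricted to the tied stages; a residual tie falls back to the fixed
    stage order.
    """
    votes = list(stage_votes)
    if not votes:
        raise ValidationError("empty vote list")
    counts = {s: 0 for s in AASM_STAGES}
    for v in votes:
        if v not in counts:
            raise ValidationError(f"unknown stage vote {v!r}")
        counts[v] += 1
    top = max(counts.values())
    tied = [s for s in AASM_STAGES if counts[s] == top]
    if len(tied) == 1 or posteriors is None:
        return tied[0]
    post = np.asarray(posteriors, dtype=np.float64)
    if post.shape[0] != len(votes):
        raise ValidationError("posteriors must align with votes")
    mass = post.sum(axis=0)
    best = max(tied, key=lambda s: mass[AASM_STAGES.index(s)])
    return best


def ensemble_posteriors(
    spec: EnsembleSpec, rec: RecordingPatterns
) -> list[np.ndarray]:
    """Per-member posterior matrices (M, 5) for one recording."""
    return [m.predict_proba(rec) for m, _ in spec.members]


def ensemble_predict(
    spec: EnsembleSpec,
    rec: RecordingPatterns,
    member_posteriors: Optional[Sequence[np.ndarray]] = None,
) -> Hypnogram:
    """Majority-vote prediction over all epochs of one recording.

    ``member_posteriors`` allows reuse of posteriors already computed by the
    cross-prediction experiment; when omitted they are computed here.
    """
    posts = (
        list(member_posteriors)
        if member_posteriors is not None
        else ensemble_posteriors(spec, rec)
    )
    if len(posts) != len(spec.members):
        raise ValidationError("one posterior matrix per member required")
    M = posts[0].shape[0]
    stages = []
    for k in range(M):
        epoch_posts = [p[k] for p in posts]
        votes = [AASM_STAGES[int(np.argmax(p))] for p in epoch_posts]
        stages.append(majority_vote(votes, epoch_posts))
    return Hypnogram(stages=stages)
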