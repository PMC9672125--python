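"""Majority-voting fusion of aligned binary prediction masks.

A voxel of the fused mask is foreground when at least ``k`` of the ``n``
voters mark it.  Voting schemes may nest: the 3.5Dv3 scheme's first voter
is itself the 2.5Dv vote of the three orthogonal 2D models, which is not
equivalent to flattening all five voters into one ballot.

Built-in schemes (voter names follow the multi-view model naming):

========  =============================================  ===
name      voters                                         k
========  =============================================  ===
2.5Dv     2Da, 2Dc, 2Ds                                  2
3.5Dv3    (2.5Dv), 2.5Da, 3D                             2
3.5Dv4    2Da, 2Dc, 2Ds, 3D                              3
3.5Dv5    2Da, 2Dc, 2Ds, 2.5Da, 3D                       3
========  =============================================  ===

With four voters a strict majority (k = 3) is required, so a 2-2 tie is
negative — the conservative choice when the point of voting is to remove
false positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np
from scipy import stats

from .errors import (
    ConsistencyError,
    ParameterError,
    SchemeError,
    VoterLookupError,
)
from .io_preprocess import BinaryMask

Voter = Union[str, "VotingScheme"]


@dataclass
class PredictionSet:
    """Named collection of aligned binary masks, one per model."""

    masks: dict[str, BinaryMask]

    def __post_init__(self) -> None:
        if not self.masks:
            raise ParameterError("prediction set needs at least one mask")
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) != 1:
            raise ConsistencyError(f"masks disagree in shape: {sorted(shapes)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.masks.values())).shape


@dataclass
class VotingScheme:
    """Declarative voting recipe; voters are model names or nested schemes.

    ``k`` defaults to a strict majority, floor(n/2) + 1.
    """

    name: str
    voters: Sequence[Voter]
    k: int | None = None

    def __post_init__(self) -> None:
        if not self.voters:
            raise SchemeError(f"scheme {self.name!r} has no voters")
        n = len(self.voters)
        if self.k is None:
            self.k = n // 2 + 1
        if not 1 <= self.k <= n:
            raise ParameterError(
                f"scheme {self.name!r}: k={self.k} outside [1, {n}]"
            )


def builtin_schemes() -> dict[str, VotingScheme]:
    """The four stock schemes (fresh objects, safe to modify)."""
    v25 = VotingScheme("2.5Dv", ["2Da", "2Dc", "2Ds"], k=2)
    return {
        "2.5Dv": v25,
        "3.5Dv3": VotingScheme("3.5Dv3", [v25, "2.5Da", "3D"], k=2),
        "3.5Dv4": VotingScheme("3.5Dv4", ["2Da", "2Dc", "2Ds", "3D"], k=3),
        "3.5Dv5": VotingScheme("3.5Dv5", ["2Da", "2Dc", "2Ds", "2.5Da", "3D"], k=3),
    }


def majority_vote(masks: Sequence[BinaryMask], k: int) -> BinaryMask:
    """Fuse masks: output voxel is 1 iff at least ``k`` inputs are 1 there."""
    if not masks:
        raise ParameterError("need at least one mask")
    shapes = {m.shape for m in masks}
    if len(shapes) != 1:
        raise ConsistencyError(f"masks disagree in shape: {sorted(shapes)}")
    n = len(masks)
    if not 1 <= k <= n:
        raise ParameterError(f"k={k} outside [1, {n}]")
    votes = np.zeros(masks[0].shape, dtype=np.int32)
    for m in masks:
        votes += m.data
    return BinaryMask(data=votes >= k, spacing=masks[0].spacing)


def apply_scheme(
    preds: PredictionSet,
    scheme: VotingScheme | str,
    *,
    extra_schemes: Mapping[str, VotingScheme] | None = None,
) -> BinaryMask:
    """Evaluate a (possibly nested) voting scheme depth-first.

    ``scheme`` may be a VotingScheme or the name of a built-in one.  String
    voters are looked up first in ``preds``, then among named schemes —
    so the stock 3.5Dv3 works directly on a five-model prediction set.
    """
    registry = dict(builtin_schemes())
    if extra_schemes:
        registry.update(extra_schemes)
    if isinstance(scheme, str):
        if scheme not in registry:
            raise VoterLookupError(f"unknown scheme {scheme!r}")
        scheme = registry[scheme]
    return _eval(scheme, preds, registry, active=set())


def _eval(
    scheme: VotingScheme,
    preds: PredictionSet,
    registry: Mapping[str, VotingScheme],
    active: set[int],
) -> BinaryMask:
    if id(scheme) in active:
        raise SchemeError(f"cyclic nesting through scheme {scheme.name!r}")
    active = active | {id(scheme)}
    ballots: list[BinaryMask] = []
    for voter in scheme.voters:
        if isinstance(voter, VotingScheme):
            ballots.append(_eval(voter, preds, registry, active))
        elif voter in preds.masks:
            ballots.append(preds.masks[voter])
        elif voter in registry:
            ballots.append(_eval(registry[voter], preds, registry, active))
        else:
            raise VoterLookupError(
                f"voter {voter!r} not in prediction set {sorted(preds.masks)}"
            )
    return majority_vote(ballots, scheme.k)  # type: ignore[arg-type]


def fp_suppression_curve(n_voters: int, per_voter_fp: float, k: int) -> float:
    """Expected voted false-positive rate under independent voter errors.

    With each voter firing falsely at a background voxel with probability
    p, the k-of-n vote fires with the binomial tail P(X >= k),
    X ~ Binomial(n, p).
    """
    if not 0.0 <= per_voter_fp <= 1.0:
        raise ParameterError(f"probability must be in [0, 1], got {per_voter_fp}")
    if not 1 <= k <= n_voters:
        raise ParameterError(f"k={k} outside [1, {n_voters}]")
    return float(stats.binom.sf(k - 1, n_voters, per_voter_fp))


def scheme_from_dict(d: Mapping) -> VotingScheme:
    """Build a scheme from a plain mapping (YAML-friendly).

    Keys: ``name``, ``voters`` (names or nested mappings), optional ``k``.
    """
    voters: list[Voter] = []
    for v in d["voters"]:
        voters.append(scheme_from_dict(v) if isinstance(v, Mapping) else str(v))
    return VotingScheme(name=str(d["name"]), voters=voters, k=d.get("k"))
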