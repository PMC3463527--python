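"""Blinding audit: discovery stages must only ever see training samples.

A :class:`BlindingAudit` is constructed with the set of sample ids a stage
group is allowed to touch (the training split).  Discovery operations call
:meth:`BlindingAudit.check` with the ids they are about to use; any id
outside the allowed set raises :class:`BlindingViolation` and the access is
recorded so the violation appears in the run's provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence


class BlindingViolation(RuntimeError):
    """A discovery-stage operation touched held-out sample ids."""


@dataclass
class BlindingAudit:
    allowed_ids: frozenset[str]
    log: list[dict] = field(default_factory=list)

    @classmethod
    def for_training(cls, training_ids: Iterable[str]) -> "BlindingAudit":
        return cls(frozenset(training_ids))

    def check(self, stage: str, sample_ids: Sequence[str]) -> None:
        ids = set(sample_ids)
        forbidden = sorted(ids - self.allowed_ids)
        self.log.append(
            {"stage": stage, "n_ids": len(ids), "violation": bool(forbidden)}
        )
        if forbidden:
            raise BlindingViolation(
                f"stage {stage!r} touched {len(forbidden)} held-out sample id(s), "
                f"e.g. {forbidden[:5]}"
            )
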