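"""Response-type and column-unit vocabulary.

A joint species-trait distribution model stacks several response columns per
species into one multiresponse matrix: an occurrence column (presence-absence,
probit family), an abundance-conditional-on-presence column (hurdle positive
part, log-normal family) and any number of site-level trait columns (log-normal
family).  Each column of the assembled matrix is a *column-unit*: a
(species, response type) pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "ResponseType",
    "ColumnUnit",
    "case_study_rtypes",
    "validate_rtypes",
    "BERNOULLI_PROBIT",
    "LOGNORMAL",
]

BERNOULLI_PROBIT = "bernoulli_probit"
LOGNORMAL = "lognormal"

_ROLES = ("occurrence", "abundance", "trait")


@dataclass(frozen=True)
class ResponseType:
    """One response type (the z index): its name, observation family and role.

    Parameters
    ----------
    name : str
        Label, e.g. ``"PA"``, ``"ABUC"``, ``"SLA"``.
    family : str
        ``"bernoulli_probit"`` (occurrence) or ``"lognormal"``.
    transform : str
        ``"identity"`` for occurrence columns, ``"log"`` for log-normal ones.
    role : str
        ``"occurrence"`` | ``"abundance"`` | ``"trait"``.  Determines which
        input table feeds the column: occurrence and abundance derive from the
        abundance table (hurdle decomposition), traits from their own tables.
    """

    name: str
    family: str
    transform: str = "log"
    role: str = field(default="")

    def __post_init__(self) -> None:
        if self.family not in (BERNOULLI_PROBIT, LOGNORMAL):
            raise ValueError(f"unknown family {self.family!r}")
        role = self.role
        if not role:
            if self.family == BERNOULLI_PROBIT:
                role = "occurrence"
            elif self.name.upper() == "ABUC":
                role = "abundance"
            else:
                role = "trait"
            object.__setattr__(self, "role", role)
        if self.role not in _ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.role == "occurrence":
            if self.family != BERNOULLI_PROBIT:
                raise ValueError("occurrence response must be bernoulli_probit")
            object.__setattr__(self, "transform", "identity")
        elif self.family == BERNOULLI_PROBIT:
            raise ValueError("bernoulli_probit family is reserved for occurrence")

    @property
    def is_probit(self) -> bool:
        return self.family == BERNOULLI_PROBIT


@dataclass(frozen=True)
class ColumnUnit:
    """A (species j, response type z) pair addressing one matrix column."""

    species: str
    rtype: ResponseType

    @property
    def label(self) -> str:
        return f"{self.species}/{self.rtype.name}"


def case_study_rtypes(trait_names: Sequence[str] = ("SLA", "LA", "MH")) -> list[ResponseType]:
    """The tundra case-study configuration: PA, ABUC plus three leaf/height traits."""
    rts = [
        ResponseType("PA", BERNOULLI_PROBIT, "identity", "occurrence"),
        ResponseType("ABUC", LOGNORMAL, "log", "abundance"),
    ]
    rts += [ResponseType(t, LOGNORMAL, "log", "trait") for t in trait_names]
    return rts


def validate_rtypes(rtypes: Sequence[ResponseType]) -> None:
    names = [r.name for r in rtypes]
    if len(set(names)) != len(names):
        raise ValueError(f"response type names not unique: {names}")
    n_occ = sum(r.role == "occurrence" for r in rtypes)
    if n_occ > 1:
        raise ValueError("at most one occurrence response type allowed")
    n_ab = sum(r.role == "abundance" for r in rtypes)
    if n_ab > 1:
        raise ValueError("at most one abundance response type allowed")
    if n_ab and not n_occ:
        raise ValueError("abundance (hurdle positive part) requires an occurrence type")
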