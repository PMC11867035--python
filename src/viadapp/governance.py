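"""Multi-tier action codes and nested governance arrangements.

Adaptation actions are identified by a multi-tier code drawn from Ostrom's
social-ecological systems taxonomy: a first-tier attribute category (settings
``S``, resource system ``RS``, resource units ``RU``, governance system
``GS``, actors ``A``, interactions ``I``, outcomes ``O``), a second-tier
attribute index within the category, optional trigger and target roles, and
an optional institutional level (operational ``OCA``, collective ``KCA``,
constitutional ``CCA``, meta-constitutional ``MCA``) with an arrangement
transition.

Text grammar (defined by this module)::

    U[_{level}[:{from}->{to}]]_[{trigger}->]{target}:{tier1}{tier2}
    U[_{level}[:{from}->{to}]]_{tier1}{tier2}

Examples: ``U_C->E:A2`` (conservation role acts on the socio-economic
attributes of the exploitation role), ``U_OCA:1->2_C->E:A2`` (the same action
re-tuned when operational arrangement 1 adapts into arrangement 2).

A nested arrangement ``CCAi|KCAj`` is encoded as a role mask (which of E, C,
P hold eligibility), a link mask over the CIS action sets, and an optional
operational specification fixing chosen intensities for the free operational
rates.  :func:`arrangement_weights` turns an arrangement plus a base weight
set into the concrete :class:`~viadapp.cisf_core.ActionWeights` that drive
the dynamics, preserving the sum-to-1 contracts by proportional
renormalization.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .cisf_core import (
    ActionWeights,
    C_SUM_FIELDS,
    E_SUM_FIELDS,
    FREE_WEIGHT_FIELDS,
    P_SUM_FIELDS,
    check_normalization,
)

__all__ = [
    "TIER2_LIMITS",
    "LINK_SETS",
    "ROLE_LINKS",
    "ActionCode",
    "parse_action_code",
    "format_action_code",
    "OCASpec",
    "Arrangement",
    "arrangement_weights",
    "diff_arrangements",
    "validate_nesting",
]

#: Number of second-tier attributes per first-tier category.
TIER2_LIMITS = {"S": 7, "RS": 10, "RU": 7, "GS": 10, "A": 9, "I": 10, "O": 3}

_ROLES = ("E", "C", "P")
_TARGETS = ("E", "C", "P", "R")
_LEVELS = ("OCA", "KCA", "CCA", "MCA")

#: CIS link sets and the weight fields they gate.
LINK_SETS: dict[str, tuple[str, ...]] = {
    "0a": ("u0a",),
    "0b": ("u0b",),
    "0c": ("u0c",),
    "0d": ("u0d",),
    "1": ("u1a", "u1b"),
    "2": ("u2a", "u2b"),
    "3": ("u3a", "u3b"),
    "4": ("u4a", "u4b"),
    "5": ("u5a", "u5b", "u5a_prime", "u5b_prime"),
    "6": ("u6a", "u6b", "u6b_prime"),
    "7R": ("u7a", "u7b"),
    "7E": ("u7c", "u7d"),
    "7P": ("u7e", "u7f"),
    "7C": ("u7g", "u7h"),
}

#: Link sets incident to each social role; deactivating a role deactivates
#: all of these.
ROLE_LINKS: dict[str, tuple[str, ...]] = {
    "E": ("0b", "1", "2", "5", "6", "7E"),
    # the settings->policy inflow (7P) is driven through the conservation
    # capacity in the dynamics, so it is incident to C as well as P
    "C": ("0d", "3", "4", "5", "6", "7C", "7P"),
    "P": ("0c", "2", "3", "7P"),
}

#: Representative action code per link set, used when expressing arrangement
#: differences as adaptation actions: (tier1, tier2, trigger, target).
_LINK_ACTION = {
    "0a": ("RU", 2, None, "R"),
    "0b": ("A", 6, "E", "E"),
    "0c": ("A", 6, "P", "P"),
    "0d": ("A", 6, "C", "C"),
    "1": ("I", 1, "E", "R"),
    "2": ("I", 9, "P", "E"),
    "3": ("I", 3, "P", "C"),
    "4": ("I", 9, "C", "R"),
    "5": ("I", 9, "C", "E"),
    "6": ("I", 7, "E", "C"),
    "7R": ("S", 4, None, "R"),
    "7E": ("S", 4, None, "E"),
    "7P": ("S", 4, None, "P"),
    "7C": ("S", 4, None, "C"),
}


@dataclass(frozen=True)
class ActionCode:
    """One multi-tier adaptation-action identifier."""

    tier1: str
    tier2_index: int
    trigger_role: Optional[str] = None
    target_role: Optional[str] = None
    level: Optional[str] = None
    level_transition: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.tier1 not in TIER2_LIMITS:
            raise ValueError(f"unknown tier-1 category {self.tier1!r}")
        limit = TIER2_LIMITS[self.tier1]
        if not 1 <= self.tier2_index <= limit:
            raise ValueError(
                f"tier-2 index {self.tier2_index} out of range 1..{limit} "
                f"for category {self.tier1}"
            )
        if self.trigger_role is not None and self.trigger_role not in _ROLES:
            raise ValueError(f"unknown trigger role {self.trigger_role!r}")
        if self.target_role is not None and self.target_role not in _TARGETS:
            raise ValueError(f"unknown target role {self.target_role!r}")
        if self.level is not None and self.level not in _LEVELS:
            raise ValueError(f"unknown arrangement level {self.level!r}")
        if self.level_transition is not None and self.level is None:
            raise ValueError("level_transition requires a level")


_CODE_RE = re.compile(
    r"^U"
    r"(?:_(?P<level>OCA|KCA|CCA|MCA)(?::(?P<from>\d+)->(?P<to>\d+))?)?"
    r"_(?:(?P<trigger>[A-Z]+)->)?"
    r"(?:(?P<target>[A-Z]+):)?"
    r"(?P<tier1>S|RS|RU|GS|A|I|O)(?P<tier2>\d+)$"
)


def parse_action_code(text: str) -> ActionCode:
    """Parse the text form of an action code; errors name the bad component."""
    m = _CODE_RE.match(text.strip())
    if m is None:
        raise ValueError(f"cannot parse action code {text!r}")
    trigger = m.group("trigger")
    if trigger is not None and trigger not in _ROLES:
        raise ValueError(f"unknown trigger role {trigger!r} in {text!r}")
    target = m.group("target")
    if target is not None and target not in _TARGETS:
        raise ValueError(f"unknown target role {target!r} in {text!r}")
    transition = None
    if m.group("from") is not None:
        transition = (int(m.group("from")), int(m.group("to")))
    return ActionCode(
        tier1=m.group("tier1"),
        tier2_index=int(m.group("tier2")),
        trigger_role=trigger,
        target_role=target,
        level=m.group("level"),
        level_transition=transition,
    )


def format_action_code(code: ActionCode) -> str:
    """Canonical text form; ``parse_action_code`` round-trips it."""
    parts = ["U"]
    if code.level is not None:
        s = f"_{code.level}"
        if code.level_transition is not None:
            s += f":{code.level_transition[0]}->{code.level_transition[1]}"
        parts.append(s)
    body = "_"
    if code.trigger_role is not None:
        body += f"{code.trigger_role}->"
    if code.target_role is not None:
        body += f"{code.target_role}:"
    body += f"{code.tier1}{code.tier2_index}"
    parts.append(body)
    return "".join(parts)


@dataclass(frozen=True)
class OCASpec:
    """Admissible range and chosen intensity for one operational rate."""

    lower: float
    upper: float
    value: float

    def __post_init__(self) -> None:
        if not self.lower <= self.value <= self.upper:
            raise ValueError(
                f"chosen intensity {self.value} outside admissible "
                f"range [{self.lower}, {self.upper}]"
            )


@dataclass(frozen=True)
class Arrangement:
    """One nested CCA|KCA|OCA governance configuration."""

    identifier: str
    cca_index: int
    kca_index: int
    role_mask: Mapping[str, bool]
    link_mask: Mapping[str, bool]
    oca_spec: Mapping[str, OCASpec] = field(default_factory=dict)
    oca_index: Optional[int] = None

    def __post_init__(self) -> None:
        if set(self.role_mask) != set(_ROLES):
            raise ValueError("role_mask must cover exactly the roles E, C, P")
        unknown = set(self.link_mask) - set(LINK_SETS)
        if unknown:
            raise ValueError(f"unknown link sets in link_mask: {sorted(unknown)}")
        # "inactive role => incident links inactive" holds by construction:
        # effective_link() conjoins the link flag with its incident role flags.
        for name in self.oca_spec:
            if name not in FREE_WEIGHT_FIELDS:
                raise ValueError(
                    f"OCA intensity may only target free operational rates, "
                    f"not {name!r} (bound by a sum-to-1 contract)"
                )
        if self.oca_index is None:
            object.__setattr__(self, "oca_index", self.kca_index)

    def effective_link(self, link: str) -> bool:
        """A link is active iff flagged active and all incident roles are."""
        if not self.link_mask.get(link, True):
            return False
        for role, links in ROLE_LINKS.items():
            if link in links and not self.role_mask[role]:
                return False
        return True

    def active_links(self) -> tuple[str, ...]:
        return tuple(l for l in LINK_SETS if self.effective_link(l))


def _renormalize_group(values: dict[str, float], group: Sequence[str],
                       identifier: str, role: str, active: bool) -> None:
    if not active:
        # An inactive compartment is inert (capacity pinned at 0); collapse
        # its incoming budget onto the self-loop so the sum-to-1 contract
        # remains checkable uniformly across arrangements.
        self_loop = group[0]
        for name in group:
            values[name] = 0.0
        values[self_loop] = 1.0
        return
    total = sum(values[name] for name in group)
    if abs(total) < 1e-12:
        raise ValueError(
            f"arrangement {identifier}: role {role} is active but its masks "
            f"leave no incoming weight to renormalize"
        )
    for name in group:
        values[name] = values[name] / total


def arrangement_weights(arrangement: Arrangement, base: ActionWeights) -> ActionWeights:
    """Concrete action weights for an arrangement applied to a base set.

    Masked-off link weights are zeroed, chosen OCA intensities are installed
    on their (free) operational rates, and each active compartment's incoming
    weights are rescaled proportionally so the sum-to-1 contracts still hold.
    The operation is idempotent: re-applying the same arrangement to its own
    output is a no-op.
    """
    report = check_normalization(base)
    if not report.passed:
        raise ValueError(
            f"base weights fail normalization: sums E={report.e_sum:.6f} "
            f"P={report.p_sum:.6f} C={report.c_sum:.6f}, "
            f"range violations {list(report.range_violations)}"
        )
    values = base.as_dict()
    for link, fields_ in LINK_SETS.items():
        if not arrangement.effective_link(link):
            for name in fields_:
                values[name] = 0.0
    field_to_link = {f: l for l, fs in LINK_SETS.items() for f in fs}
    for name, spec in arrangement.oca_spec.items():
        # an intensity on a masked-off link stays off
        if arrangement.effective_link(field_to_link[name]):
            values[name] = spec.value
    _renormalize_group(values, E_SUM_FIELDS, arrangement.identifier, "E",
                       arrangement.role_mask["E"])
    _renormalize_group(values, P_SUM_FIELDS, arrangement.identifier, "P",
                       arrangement.role_mask["P"])
    _renormalize_group(values, C_SUM_FIELDS, arrangement.identifier, "C",
                       arrangement.role_mask["C"])
    return ActionWeights.from_dict(values)


def diff_arrangements(a: Arrangement, b: Arrangement) -> frozenset[ActionCode]:
    """Adaptation actions at the highest institutional level where a and b differ.

    A constitutional difference (different CCA index) dominates a collective
    one (different link masks), which dominates an operational one (different
    chosen intensities).  Each returned code carries the level transition
    ``(a, b)``.
    """
    if a.cca_index != b.cca_index:
        transition = (a.cca_index, b.cca_index)
        codes = set()
        for role in _ROLES:
            if a.role_mask[role] != b.role_mask[role]:
                codes.add(ActionCode("GS", 7, trigger_role="P", target_role=role,
                                     level="CCA", level_transition=transition))
        if not codes:
            codes.add(ActionCode("GS", 7, trigger_role="P",
                                 level="CCA", level_transition=transition))
        return frozenset(codes)

    changed_links = {
        link for link in LINK_SETS
        if a.effective_link(link) != b.effective_link(link)
    }
    if changed_links:
        transition = (a.kca_index, b.kca_index)
        codes = set()
        for link in changed_links:
            tier1, tier2, trigger, target = _LINK_ACTION[link]
            codes.add(ActionCode(tier1, tier2, trigger_role=trigger,
                                 target_role=target, level="KCA",
                                 level_transition=transition))
        return frozenset(codes)

    changed_rates = {
        name for name in set(a.oca_spec) | set(b.oca_spec)
        if (a.oca_spec.get(name).value if name in a.oca_spec else None)
        != (b.oca_spec.get(name).value if name in b.oca_spec else None)
    }
    if changed_rates:
        transition = (a.oca_index, b.oca_index)
        codes = set()
        for name in changed_rates:
            link = next(l for l, fs in LINK_SETS.items() if name in fs)
            tier1, tier2, trigger, target = _LINK_ACTION[link]
            codes.add(ActionCode(tier1, tier2, trigger_role=trigger,
                                 target_role=target, level="OCA",
                                 level_transition=transition))
        return frozenset(codes)
    return frozenset()


def validate_nesting(arrangements: Iterable[Arrangement]) -> None:
    """Check the structural nesting relation over a set of arrangements.

    Every KCA index must belong to exactly one CCA and every OCA index to
    exactly one KCA.
    """
    kca_to_cca: dict[int, int] = {}
    oca_to_kca: dict[int, int] = {}
    for arr in arrangements:
        if kca_to_cca.setdefault(arr.kca_index, arr.cca_index) != arr.cca_index:
            raise ValueError(
                f"KCA {arr.kca_index} appears under more than one CCA"
            )
        if oca_to_kca.setdefault(arr.oca_index, arr.kca_index) != arr.kca_index:
            raise ValueError(
                f"OCA {arr.oca_index} appears under more than one KCA"
            )
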