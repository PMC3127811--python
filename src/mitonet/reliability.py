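"""Data-integrative reliability evaluation of identified proteins.

Identified proteins are tiered by independent evidence of mitochondrial
localization.  The *reference* tier holds proteins carrying the organelle
cellular-component annotation and found in at least one curated reference
catalog (by default both criteria are required; an ``or`` rule is also
available because either reading of the evidence combination is defensible).
Proteins outside the reference tier are rescued if they have at least one
physical-channel link to a reference-tier protein (*physical* tier) or,
failing that, at least one functional-channel link (*functional* tier);
physical evidence takes precedence, so the tiers are disjoint.  Rescue is
single-hop: links to rescued proteins do not propagate.  Everything else is
*non-referenced*.  The union of the first three tiers is the reliable set
carried forward to network analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Set

import pandas as pd

logger = logging.getLogger(__name__)

PHYSICAL = "physical"
FUNCTIONAL = "functional"
CHANNELS = (PHYSICAL, FUNCTIONAL)

LINK_COLUMNS = ("protein_a", "protein_b", "confidence", "channel")


@dataclass(frozen=True)
class ReferenceCatalog:
    """Organelle annotation plus named reference protein sets.

    ``cc_annotated`` is the set of ids carrying the cellular-component
    annotation; ``reference_sets`` maps catalog names to id sets (emulating
    independent mitochondrial databases and proteomics datasets).
    """

    cc_annotated: frozenset
    reference_sets: Mapping[str, frozenset]

    @property
    def any_reference(self) -> frozenset:
        out: Set[str] = set()
        for s in self.reference_sets.values():
            out |= set(s)
        return frozenset(out)


@dataclass(frozen=True)
class ReliabilityTiers:
    """Disjoint partition of the identified-protein universe."""

    tier_reference: frozenset
    tier_physical: frozenset
    tier_functional: frozenset
    non_referenced: frozenset

    def __post_init__(self) -> None:
        tiers = [
            self.tier_reference,
            self.tier_physical,
            self.tier_functional,
            self.non_referenced,
        ]
        total = sum(len(t) for t in tiers)
        if len(frozenset().union(*tiers)) != total:
            raise ValueError("reliability tiers are not pairwise disjoint")

    @property
    def reliable(self) -> frozenset:
        return self.tier_reference | self.tier_physical | self.tier_functional

    @property
    def universe(self) -> frozenset:
        return self.reliable | self.non_referenced


def assign_reference_tier(
    protein_ids: Iterable[str],
    catalog: ReferenceCatalog,
    rule: str = "and",
) -> frozenset:
    """Select identified proteins supported by the reference catalog.

    With ``rule="and"`` (default) a protein must carry the organelle
    annotation *and* occur in at least one reference set; with ``rule="or"``
    either line of evidence suffices.
    """
    if rule not in ("and", "or"):
        raise ValueError(f"rule must be 'and' or 'or', got {rule!r}")
    if not catalog.cc_annotated and not catalog.reference_sets:
        raise ValueError("reference catalog is empty")
    ids = set(protein_ids)
    in_any = catalog.any_reference
    if rule == "and":
        return frozenset(i for i in ids if i in catalog.cc_annotated and i in in_any)
    return frozenset(i for i in ids if i in catalog.cc_annotated or i in in_any)


def assign_link_tiers(
    protein_ids: Iterable[str],
    tier_reference: Iterable[str],
    links: pd.DataFrame,
) -> ReliabilityTiers:
    """Rescue non-reference proteins through links to the reference tier.

    ``links`` is a table with columns ``protein_a, protein_b, confidence,
    channel``.  Link rows with an endpoint outside the identified universe
    are ignored (count logged).
    """
    universe = set(protein_ids)
    reference = frozenset(tier_reference)
    if not reference <= universe:
        raise ValueError("tier_reference contains ids outside the universe")

    physical_neighbors: Set[str] = set()
    functional_neighbors: Set[str] = set()
    n_ignored = 0
    for a, b, channel in zip(links["protein_a"], links["protein_b"], links["channel"]):
        if a not in universe or b not in universe:
            n_ignored += 1
            continue
        for x, y in ((a, b), (b, a)):
            if x not in reference and y in reference:
                if channel == PHYSICAL:
                    physical_neighbors.add(x)
                elif channel == FUNCTIONAL:
                    functional_neighbors.add(x)
                else:
                    raise ValueError(f"unknown link channel {channel!r}")
    if n_ignored:
        logger.info(
            "ignored %d link rows with endpoints outside the identified universe",
            n_ignored,
        )
    tier_physical = frozenset(physical_neighbors)
    tier_functional = frozenset(functional_neighbors - tier_physical)
    non_referenced = frozenset(universe - reference - tier_physical - tier_functional)
    return ReliabilityTiers(
        tier_reference=reference,
        tier_physical=tier_physical,
        tier_functional=tier_functional,
        non_referenced=non_referenced,
    )


def reliability_report(tiers: ReliabilityTiers) -> pd.DataFrame:
    """Per-tier counts and percentages of the identified universe.

    Percentages are rounded to two decimals; a ``reliable`` summary row
    (reference + physical + functional) is appended.
    """
    n_total = len(tiers.universe)

    def pct(n: int) -> float:
        return round(100.0 * n / n_total, 2) if n_total else 0.0

    rows = [
        ("reference", len(tiers.tier_reference)),
        ("physical", len(tiers.tier_physical)),
        ("functional", len(tiers.tier_functional)),
        ("non_referenced", len(tiers.non_referenced)),
        ("reliable", len(tiers.reliable)),
    ]
    return pd.DataFrame(
        {
            "tier": [r[0] for r in rows],
            "count": [r[1] for r in rows],
            "percent": [pct(r[1]) for r in rows],
        }
    )
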