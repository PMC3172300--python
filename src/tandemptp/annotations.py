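"""Motif and functionally-important-residue (FIR) annotations.

The PTP fold is described by ten conserved sequence motifs. Motif 1
carries the phosphotyrosine-recognition residues (the "head" of the
contact-map butterfly pattern), motifs 2-7 form the structural core
("body and wings"), and motifs 8-10 — the WPD loop, the active-site
P-loop region and the Q loop — form the "tail". Twenty functionally
important residues (FIRs) fall into five groups: active site, substrate
recognition, WPD loop, Q loop, and the R loop plus the conserved
glutamate.

Residue numbering differs between constructs and homology models, so both
motif ranges and FIR identities are user-supplied configuration (YAML),
never hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

__all__ = [
    "MotifAnnotation",
    "FIRSet",
    "FIR_GROUPS",
    "load_motifs",
    "load_firs",
    "demo_motifs",
    "demo_firs",
]

#: The five canonical FIR groups.
FIR_GROUPS = (
    "active_site",
    "substrate_recognition",
    "WPD_loop",
    "Q_loop",
    "R_loop_and_Glu",
)

#: Default butterfly-region label per motif id.
DEFAULT_REGIONS = {1: "head", **{m: "body-wings" for m in range(2, 8)},
                   **{m: "tail" for m in range(8, 11)}}


@dataclass
class MotifAnnotation:
    """Maps motif ids (1-10) to residue index ranges.

    ``ranges`` maps motif id -> list of ``(start, stop)`` half-open ranges
    of global 0-based residue indices. Ranges must not overlap. Region
    labels default to the butterfly convention (head / body-wings / tail)
    and can be overridden per motif.
    """

    ranges: dict[int, list[tuple[int, int]]]
    regions: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        covered: set[int] = set()
        for motif_id, rngs in self.ranges.items():
            for start, stop in rngs:
                if stop < start:
                    raise ValueError(f"motif {motif_id}: inverted range {start}:{stop}")
                block = set(range(start, stop))
                if covered & block:
                    raise ValueError(f"motif {motif_id}: overlapping residue ranges")
                covered |= block

    def residues_by_motif(self) -> dict[int, list[int]]:
        return {
            m: [r for start, stop in rngs for r in range(start, stop)]
            for m, rngs in sorted(self.ranges.items())
        }

    def motif_of(self) -> dict[int, int]:
        """Residue index -> motif id for every annotated residue."""
        out: dict[int, int] = {}
        for m, residues in self.residues_by_motif().items():
            for r in residues:
                out[r] = m
        return out

    def region_of(self, motif_id: int) -> str:
        return self.regions.get(motif_id, DEFAULT_REGIONS.get(motif_id, "unassigned"))


@dataclass
class FIRSet:
    """The named functionally important residues with their group labels.

    ``members`` maps a residue name (e.g. ``"C1638"``) to a
    ``(residue_index, group)`` pair, with group one of :data:`FIR_GROUPS`.
    A canonical FIR set has 20 residues covering all five groups;
    ``expected_size`` can be lowered for partial, user-declared sets.
    """

    members: dict[str, tuple[int, str]]
    expected_size: int = 20

    def __post_init__(self) -> None:
        bad = {g for _, g in self.members.values()} - set(FIR_GROUPS)
        if bad:
            raise ValueError(f"unknown FIR groups: {sorted(bad)}; allowed: {FIR_GROUPS}")
        if len(self.members) != self.expected_size:
            raise ValueError(
                f"FIR set has {len(self.members)} residues, expected {self.expected_size}"
            )

    @property
    def residues(self) -> list[int]:
        return [idx for idx, _ in self.members.values()]

    def group_of(self) -> dict[int, str]:
        return {idx: group for idx, group in self.members.values()}

    def groups_present(self) -> set[str]:
        return {g for _, g in self.members.values()}


def load_motifs(path) -> MotifAnnotation:
    """Load motif ranges from YAML.

    Expected layout::

        motifs:
          1: [[0, 4]]
          2: [[6, 10], [12, 14]]
        regions:          # optional overrides
          1: head
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    ranges = {
        int(m): [tuple(int(x) for x in rng) for rng in rngs]
        for m, rngs in doc["motifs"].items()
    }
    regions = {int(m): str(r) for m, r in doc.get("regions", {}).items()}
    return MotifAnnotation(ranges=ranges, regions=regions)


def load_firs(path) -> FIRSet:
    """Load a FIR set from YAML.

    Expected layout::

        firs:
          C1638: {residue: 12, group: active_site}
          ...
        expected_size: 20   # optional
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    members = {
        str(name): (int(entry["residue"]), str(entry["group"]))
        for name, entry in doc["firs"].items()
    }
    return FIRSet(members=members, expected_size=int(doc.get("expected_size", 20)))


# ---------------------------------------------------------------------------
# Demo annotations for the synthetic two-domain system
# ---------------------------------------------------------------------------

def demo_motifs(n_residues: int = 30, offset: int = 0) -> MotifAnnotation:
    """Ten contiguous 3-residue motifs over a synthetic pseudo-domain.

    Covers residues ``offset .. offset + n_residues``; used by the demo
    pipeline and tests, where residue identity is arbitrary.
    """
    if n_residues < 30:
        raise ValueError("demo motifs need at least 30 residues")
    width = n_residues // 10
    ranges = {
        m: [(offset + (m - 1) * width, offset + m * width)] for m in range(1, 11)
    }
    return MotifAnnotation(ranges=ranges)


def demo_firs(offset: int = 0) -> FIRSet:
    """A 20-residue FIR set over a synthetic 30-residue pseudo-domain,
    with four residues per group placed inside the motifs conventionally
    hosting that group (motif 1 -> recognition, motif 8 -> WPD loop, ...).
    """
    layout = {
        "substrate_recognition": [0, 1, 2, 4],   # head, motif 1-2
        "active_site": [12, 13, 14, 16],          # core, motifs 5-6
        "WPD_loop": [21, 22, 23, 20],             # motif 8 neighbourhood
        "Q_loop": [27, 28, 29, 26],               # motif 10
        "R_loop_and_Glu": [24, 25, 18, 19],       # motifs 7-9
    }
    members = {}
    for group, residues in layout.items():
        for r in residues:
            members[f"{group[:3].upper()}{offset + r}"] = (offset + r, group)
    return FIRSet(members=members)
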