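"""Branch-of-origin dating of insertions on the reference lineage.

Each internal node on the path from the tree root to the reference leaf
defines a split where a group of species diverged from the reference
lineage.  Ordering those groups from most divergent to least gives a
*species ladder*.  An element is dated by scanning the ladder outside-in:
the first group in which at least half of the element's bases align to
some species places the element on the reference-lineage branch above that
group's common ancestor with the reference; if no group qualifies the
element is assigned to the youngest, reference-specific branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from exaptscan.alignio import AlignmentBlock
from exaptscan.intervals import GenomicInterval

PRESENCE_THRESHOLD = 0.5


@dataclass(frozen=True)
class SpeciesLadder:
    """Ordered species groups from most divergent to least.

    ``groups`` pairs each reference-lineage branch label with the species
    that diverged at the corresponding split; ``presence`` maps every
    branch label (including the youngest) to the full species set that
    carries an insertion originating on that branch.
    """

    groups: tuple[tuple[str, frozenset[str]], ...]
    youngest: str
    reference: str
    presence: dict[str, frozenset[str]] = field(hash=False)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for _, members in self.groups:
            if seen & members:
                raise ValueError("ladder groups must be disjoint")
            seen |= members

    @property
    def branch_labels(self) -> list[str]:
        """All branch labels, oldest first, youngest last."""
        return [label for label, _ in self.groups] + [self.youngest]

    @classmethod
    def from_newick(cls, newick: str, reference: str) -> "SpeciesLadder":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_tree(tree, reference)

    @classmethod
    def from_tree(cls, tree: dendropy.Tree, reference: str) -> "SpeciesLadder":
        """Derive the ladder from a rooted tree and its reference leaf.

        Path nodes root=v0, v1, ..., vk=reference give branch labels
        ``b0`` (above the root; insertions present in every species)
        through ``bk`` (the terminal reference branch).
        """
        ref_leaf = None
        for leaf in tree.leaf_node_iter():
            if leaf.taxon is not None and leaf.taxon.label == reference:
                ref_leaf = leaf
                break
        if ref_leaf is None:
            raise ValueError(f"reference {reference!r} not in tree")
        path = [ref_leaf]
        while path[-1].parent_node is not None:
            path.append(path[-1].parent_node)
        path.reverse()  # root ... reference leaf

        def leaves_under(node) -> frozenset[str]:
            return frozenset(l.taxon.label for l in node.leaf_iter())

        groups = []
        presence: dict[str, frozenset[str]] = {}
        for j in range(len(path) - 1):
            label = f"b{j}"
            presence[label] = leaves_under(path[j])
            sisters = leaves_under(path[j]) - leaves_under(path[j + 1])
            if sisters:
                groups.append((label, sisters))
        youngest = f"b{len(path) - 1}"
        presence[youngest] = frozenset({reference})
        return cls(
            groups=tuple(groups),
            youngest=youngest,
            reference=reference,
            presence=presence,
        )


@dataclass(frozen=True)
class BranchAssignment:
    """Dated origin of one element."""

    cnee_id: str
    branch: str
    aligned_fractions: dict[str, float] = field(hash=False)


def aligned_fraction(
    cnee: GenomicInterval,
    blocks: list[AlignmentBlock],
    species_group: frozenset[str] | set[str],
) -> float:
    """Fraction of the element's reference bases aligned (non-gap) to at
    least one species of the group.

    An element outside every block has fraction 0.
    """
    covered = np.zeros(cnee.length, dtype=bool)
    touched = False
    for block in blocks:
        if block.chrom != cnee.chrom or block.end <= cnee.start or block.start >= cnee.end:
            continue
        touched = True
        cols = block.ref_columns()
        rows = [block.sequences[sp] for sp in species_group if sp in block.sequences]
        for offset, col in enumerate(cols):
            pos = block.start + offset
            if cnee.start <= pos < cnee.end:
                if any(row[col] != "-" for row in rows):
                    covered[pos - cnee.start] = True
    if not touched:
        import warnings

        warnings.warn(f"element {cnee} outside all alignment blocks")
    return float(covered.sum() / cnee.length)


def assign_branch(
    cnee: GenomicInterval,
    blocks: list[AlignmentBlock],
    ladder: SpeciesLadder,
    cnee_id: str = "",
    threshold: float = PRESENCE_THRESHOLD,
) -> BranchAssignment:
    """Date one element by outside-in ladder scan.

    The first group (most divergent first) whose aligned fraction reaches
    ``threshold`` fixes the branch; otherwise the youngest branch.
    """
    fractions: dict[str, float] = {}
    chosen = ladder.youngest
    for label, members in ladder.groups:
        frac = aligned_fraction(cnee, blocks, members)
        fractions[label] = frac
        if frac >= threshold and chosen == ladder.youngest:
            chosen = label
    return BranchAssignment(cnee_id=cnee_id, branch=chosen, aligned_fractions=fractions)
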