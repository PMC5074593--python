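"""Mutation-set overlap with pathway residues.

Disease-associated point mutations from a homologous protein (e.g. human
MSH2/MSH6 variants mapped onto bacterial MutS through a published
alignment) can be tested for enrichment on the computed pathway residues.
Under a random placement of n_mutations positions among n_total residues,
the expected number landing on the n_pathway pathway residues is simply

    E = n_mutations * n_pathway / n_total,

and the upper-tail probability of the observed overlap follows the
hypergeometric distribution (drawing without replacement).  The tail
probability is an extension beyond the bare expectation; it is labelled
as such in reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path as FilePath
from typing import Sequence

from scipy.stats import hypergeom

from .model import NodeModel


@dataclass(frozen=True)
class MappedMutation:
    source_protein: str
    source_position: int
    target_chain: str | None  # None when unmapped
    target_resnum: int | None
    annotation: str = ""  # "on_pathway" | "adjacent" | "off_pathway" | "unmapped"
    count: int = 1  # duplicates collapsed


@dataclass
class MutationSet:
    entries: list[MappedMutation]

    @property
    def n_mapped(self) -> int:
        return sum(1 for e in self.entries if e.target_resnum is not None)

    def with_annotation(self, annotation: str) -> list[MappedMutation]:
        return [e for e in self.entries if e.annotation == annotation]


def read_alignment_table(path: str | FilePath) -> dict[int, tuple[str, int]]:
    """Two-column (or three-column with chain) TSV mapping source position
    -> target residue.  Malformed lines raise with the line number."""
    mapping: dict[int, tuple[str, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                if len(parts) == 2:
                    src, tgt = parts
                    if ":" in tgt:
                        chain, resnum = tgt.split(":")
                    else:
                        chain, resnum = "A", tgt
                elif len(parts) == 3:
                    src, chain, resnum = parts
                else:
                    raise ValueError("expected 2 or 3 tab-separated columns")
                mapping[int(src)] = (chain, int(resnum))
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed alignment table at line {lineno}: {exc}"
                ) from exc
    return mapping


def map_mutations(
    mutations: Sequence[tuple[str, int]],
    alignment: dict[int, tuple[str, int]] | str | FilePath,
    node_model: NodeModel,
    pathway_residues: set[tuple[str, int]] | None = None,
) -> MutationSet:
    """Map source-protein mutation positions onto target residues.

    Duplicate (protein, position) entries are collapsed with their count
    retained.  When ``pathway_residues`` (set of (chain, resnum)) is
    given, each mapped mutation is annotated as ``on_pathway``,
    ``adjacent`` (immediately sequence-adjacent, |Δresnum| = 1 on the same
    chain) or ``off_pathway``.
    """
    if not isinstance(alignment, dict):
        alignment = read_alignment_table(alignment)
    model_residues = {(n.chain_id, n.resnum) for n in node_model}
    counts: dict[tuple[str, int], int] = {}
    for prot, pos in mutations:
        counts[(prot, int(pos))] = counts.get((prot, int(pos)), 0) + 1
    entries: list[MappedMutation] = []
    for (prot, pos), cnt in sorted(counts.items()):
        target = alignment.get(pos)
        if target is None or target not in model_residues:
            entries.append(MappedMutation(prot, pos, None, None, "unmapped", cnt))
            continue
        chain, resnum = target
        annotation = ""
        if pathway_residues is not None:
            if (chain, resnum) in pathway_residues:
                annotation = "on_pathway"
            elif (chain, resnum - 1) in pathway_residues or (
                chain,
                resnum + 1,
            ) in pathway_residues:
                annotation = "adjacent"
            else:
                annotation = "off_pathway"
        entries.append(MappedMutation(prot, pos, chain, resnum, annotation, cnt))
    return MutationSet(entries)


@dataclass(frozen=True)
class OverlapExpectation:
    n_mutations: int
    n_pathway_residues: int
    n_total_residues: int
    expected: float
    expected_rounded: int
    observed: int | None = None
    tail_probability: float | None = None  # P(X >= observed), hypergeometric


def overlap_expectation(
    n_mutations: int,
    n_pathway_residues: int,
    n_total_residues: int,
    observed: int | None = None,
) -> OverlapExpectation:
    """Random-overlap expectation n·K/N, plus the hypergeometric upper
    tail of an observed count when provided."""
    if n_pathway_residues > n_total_residues:
        raise ValueError("n_pathway_residues exceeds n_total_residues")
    if min(n_mutations, n_pathway_residues, n_total_residues) < 0:
        raise ValueError("counts must be non-negative")
    if n_total_residues == 0:
        raise ValueError("n_total_residues must be positive")
    expected = n_mutations * n_pathway_residues / n_total_residues
    tail = None
    if observed is not None:
        # X ~ Hypergeom(N=n_total, K=n_pathway, n=n_mutations)
        tail = float(
            hypergeom.sf(
                observed - 1, n_total_residues, n_pathway_residues, n_mutations
            )
        )
    return OverlapExpectation(
        n_mutations=n_mutations,
        n_pathway_residues=n_pathway_residues,
        n_total_residues=n_total_residues,
        expected=expected,
        expected_rounded=int(round(expected)),
        observed=observed,
        tail_probability=tail,
    )
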