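"""Hsf class/subclass assignment and chromosome-ordered gene naming.

The class call rests on the HR-A/B insertion signature: 21 inserted
residues between HR-A and HR-B means class A, none means class B, 7 means
class C.  Subclasses are assigned by nearest labeled exemplar under a
Poisson-corrected distance over the concatenated DBD + HR-A/B region, which
mirrors clade membership in the family phylogeny without requiring a full
tree per query.
"""
from __future__ import annotations

import re
from dataclasses import dataclass

from .evolution import p_distance_pairwise_deletion, poisson_correct
from .features import DomainAnnotation
from .io import GeneLocus

INSERTION_TO_CLASS = {21: "A", 0: "B", 7: "C"}


@dataclass
class HsfClassLabel:
    klass: str | None            # None = unclassified
    subclass: str | None
    insertion_raw: int | None
    exemplar: str | None = None
    exemplar_distance: float | None = None


def assign_class(annotation: DomainAnnotation) -> str | None:
    """Class from the snapped HR-A/B insertion; None when unsnappable."""
    if not annotation.has_hrab:
        raise ValueError(f"{annotation.protein_id}: no HR-A/B region annotated")
    if annotation.insertion_snapped is None:
        return None
    return INSERTION_TO_CLASS[annotation.insertion_snapped]


def class_of_label(protein_type: str) -> str:
    """Leading class letter of a subclass label such as 'A4a' or 'B2d'."""
    m = re.match(r"([ABC])", protein_type)
    if not m:
        raise ValueError(f"malformed protein-type label {protein_type!r}")
    return m.group(1)


def _conserved_region(protein: str, annotation: DomainAnnotation) -> str:
    pieces = []
    if annotation.dbd:
        pieces.append(protein[annotation.dbd[0] - 1 : annotation.dbd[1]])
    if annotation.hra and annotation.hrb:
        pieces.append(protein[annotation.hra[0] - 1 : annotation.hrb[1]])
    return "".join(pieces)


def assign_subclass(protein: str, annotation: DomainAnnotation,
                    exemplars: dict[str, tuple[str, DomainAnnotation]],
                    klass: str | None = None) -> HsfClassLabel:
    """Nearest-exemplar subclass restricted to exemplars of the same class.

    ``exemplars`` maps subclass label -> (protein sequence, annotation).
    Ties break on the lexicographically smallest exemplar label.  With no
    exemplar of the class available, the label is class-only.
    """
    if klass is None:
        klass = assign_class(annotation)
    label = HsfClassLabel(klass, None, annotation.insertion_raw)
    if klass is None:
        return label
    query_region = _conserved_region(protein, annotation)
    best: tuple[float, str] | None = None
    for sub_label in sorted(exemplars):
        if class_of_label(sub_label) != klass:
            continue
        ex_protein, ex_ann = exemplars[sub_label]
        ex_region = _conserved_region(ex_protein, ex_ann)
        n = min(len(query_region), len(ex_region))
        p = p_distance_pairwise_deletion(query_region[:n], ex_region[:n])
        d = poisson_correct(p)
        dist = d if d is not None else float("inf")
        if best is None or dist < best[0]:
            best = (dist, sub_label)
    if best is not None:
        label.subclass = best[1]
        label.exemplar = best[1]
        label.exemplar_distance = best[0]
    return label


def _chromosome_key(chromosome: str) -> tuple[int, int | str]:
    """Numbered chromosomes sort naturally; unplaced groups sort last."""
    m = re.fullmatch(r"(?:chr)?0*(\d+)", chromosome, flags=re.IGNORECASE)
    if m:
        return (0, int(m.group(1)))
    return (1, chromosome)


def name_genes(loci: list[GeneLocus], prefix: str = "Hsf") -> dict[str, str]:
    """Number genes by chromosomal position: sort by (chromosome, start, id)."""
    ordered = sorted(loci, key=lambda l: (_chromosome_key(l.chromosome), l.start, l.gene_id))
    return {loc.gene_id: f"{prefix}{i}" for i, loc in enumerate(ordered, start=1)}


def chromosome_census(loci: list[GeneLocus]) -> tuple[int, int]:
    """(number of numbered chromosomes, number of unplaced linkage groups)."""
    chroms = {l.chromosome for l in loci}
    numbered = {c for c in chroms if _chromosome_key(c)[0] == 0}
    return len(numbered), len(chroms - numbered)
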