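"""Coding-consequence annotation on explicit gene models.

Coordinates are 1-based inclusive.  Two deliberately distinct coordinate
helpers exist because they answer different questions: the length of an
interval that includes both endpoints (:func:`inclusive_span`) and the
difference between two point positions (:func:`position_distance`); mixing
the two conventions is a classic source of silent off-by-one bugs.

Annotation covers the categories a pooled-mapping candidate screen needs:
stopgain, stoploss, synonymous/nonsynonymous SNVs, frameshift and
non-frameshift indels, plus noncoding/upstream/downstream placement.
Splice-site modelling and UTR subtypes are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

FUNCTIONAL_CATEGORIES = (
    "stopgain",
    "stoploss",
    "frameshift_indel",
    "nonframeshift_indel",
    "nonsynonymous",
)

#: Severity used for candidate ranking; smaller ranks are more severe.
SEVERITY_RANK = {
    "stopgain": 0,
    "frameshift_indel": 0,
    "stoploss": 1,
    "nonframeshift_indel": 2,
    "nonsynonymous": 3,
    "synonymous": 4,
    "noncoding": 5,
    "upstream": 6,
    "downstream": 6,
}


def inclusive_span(start: int, end: int) -> int:
    """Length in bp of the 1-based inclusive interval [start, end]."""
    if start < 1 or end < 1:
        raise ValueError("coordinates are 1-based; must be >= 1")
    if start > end:
        raise ValueError(f"start {start} > end {end}")
    return end - start + 1


def position_distance(pos_a: int, pos_b: int) -> int:
    """Distance in bp between two point positions (simple difference)."""
    if pos_a < 1 or pos_b < 1:
        raise ValueError("positions are 1-based; must be >= 1")
    return abs(pos_b - pos_a)


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


@dataclass
class GeneModel:
    """A protein-coding gene with explicit exon structure and sequence.

    ``seq`` is the forward-strand genomic sequence of the gene span
    (``exons[0][0] .. exons[-1][1]``).  ``cds_start``/``cds_end`` bound the
    coding sequence in genomic coordinates and must fall inside exons; the
    translated CDS includes the stop codon.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int
    seq: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError("gene model needs at least one exon")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        prev_end = 0
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"exon start {s} > end {e}")
            if s <= prev_end:
                raise ValueError("exons overlap or are unsorted")
            prev_end = e
        if len(self.seq) != self.span_end - self.span_start + 1:
            raise ValueError(
                f"sequence length {len(self.seq)} does not match gene span "
                f"{self.span_end - self.span_start + 1}"
            )
        if not (self.span_start <= self.cds_start <= self.cds_end
                <= self.span_end):
            raise ValueError("CDS bounds outside gene span")

    # -- coordinates -------------------------------------------------------

    @property
    def span_start(self) -> int:
        return self.exons[0][0]

    @property
    def span_end(self) -> int:
        return self.exons[-1][1]

    def base_at(self, pos: int) -> str:
        """Forward-strand reference base at a genomic position."""
        if not (self.span_start <= pos <= self.span_end):
            raise ValueError(f"position {pos} outside gene span")
        return self.seq[pos - self.span_start]

    def cds_genomic_positions(self) -> list[int]:
        """Genomic positions of CDS bases, ascending."""
        out = []
        for s, e in self.exons:
            lo = max(s, self.cds_start)
            hi = min(e, self.cds_end)
            if lo <= hi:
                out.extend(range(lo, hi + 1))
        return out

    def cds_sequence(self) -> str:
        """Spliced CDS in transcript orientation (5'->3')."""
        bases = "".join(self.base_at(p) for p in self.cds_genomic_positions())
        if self.strand == "-":
            bases = bases.translate(_COMPLEMENT)[::-1]
        return bases

    def protein(self) -> str:
        """Reference protein, without the terminal stop symbol."""
        cds = self.cds_sequence()
        if len(cds) % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length {len(cds)} not a "
                             "multiple of 3")
        aa = str(Seq(cds).translate())
        if not aa.endswith("*"):
            raise ValueError(f"{self.gene_id}: CDS does not end in a stop codon")
        body = aa[:-1]
        if "*" in body:
            raise ValueError(f"{self.gene_id}: internal stop in reference CDS")
        return body

    def transcript_index(self, pos: int) -> int | None:
        """0-based index of a genomic position in the spliced CDS, or None."""
        positions = self.cds_genomic_positions()
        try:
            i = positions.index(pos)
        except ValueError:
            return None
        if self.strand == "-":
            return len(positions) - 1 - i
        return i


@dataclass(frozen=True)
class EffectAnnotation:
    """Predicted consequence of one variant on one gene model."""

    gene_id: str
    category: str
    protein_change: str | None = None
    truncated_length: int | None = None
    distance: int | None = None


def annotate_variant(
    model: GeneModel, chrom: str, pos: int, ref: str, alt: str
) -> EffectAnnotation:
    """Classify a variant's coding consequence on one gene model.

    SNVs inside the CDS are translated before and after; indels inside the
    CDS are frameshift when the length change is not a multiple of 3.
    Variants in the gene span outside the CDS are ``noncoding``; variants
    outside the span are ``upstream``/``downstream`` (strand-aware) with a
    point distance to the nearest span edge.
    """
    if chrom != model.chrom:
        raise ValueError(
            f"variant on {chrom} but gene {model.gene_id} is on {model.chrom}"
        )
    ref = ref.upper()
    alt = alt.upper()

    if pos < model.span_start or pos > model.span_end:
        before = pos < model.span_start
        dist = (model.span_start - pos) if before else (pos - model.span_end)
        if model.strand == "+":
            category = "upstream" if before else "downstream"
        else:
            category = "downstream" if before else "upstream"
        return EffectAnnotation(model.gene_id, category, distance=dist)

    if len(ref) == 1 and len(alt) == 1:
        genomic_base = model.base_at(pos)
        if genomic_base.upper() != ref:
            raise ValueError(
                f"reference mismatch at {chrom}:{pos}: variant says {ref}, "
                f"gene model has {genomic_base}"
            )
        t_idx = model.transcript_index(pos)
        if t_idx is None:
            return EffectAnnotation(model.gene_id, "noncoding")
        cds = model.cds_sequence()
        mut_base = alt
        if model.strand == "-":
            mut_base = alt.translate(_COMPLEMENT)
        codon_idx = t_idx // 3
        within = t_idx % 3
        codon = cds[codon_idx * 3: codon_idx * 3 + 3]
        new_codon = codon[:within] + mut_base + codon[within + 1:]
        old_aa = str(Seq(codon).translate())
        new_aa = str(Seq(new_codon).translate())
        change = f"{old_aa}{codon_idx + 1}{new_aa}"
        if old_aa != "*" and new_aa == "*":
            return EffectAnnotation(
                model.gene_id, "stopgain", protein_change=change,
                truncated_length=codon_idx,
            )
        if old_aa == "*" and new_aa != "*":
            return EffectAnnotation(model.gene_id, "stoploss",
                                    protein_change=change)
        if old_aa == new_aa:
            return EffectAnnotation(model.gene_id, "synonymous",
                                    protein_change=change)
        return EffectAnnotation(model.gene_id, "nonsynonymous",
                                protein_change=change)

    # Indel: classify by length change when it touches the CDS.
    var_end = pos + max(len(ref) - 1, 0)
    cds_positions = model.cds_genomic_positions()
    touches_cds = any(pos <= p <= var_end for p in cds_positions)
    if not touches_cds:
        return EffectAnnotation(model.gene_id, "noncoding")
    if model.base_at(pos).upper() != ref[0]:
        raise ValueError(
            f"reference mismatch at {chrom}:{pos}: variant says {ref[0]}, "
            f"gene model has {model.base_at(pos)}"
        )
    shift = (len(alt) - len(ref)) % 3
    category = "nonframeshift_indel" if shift == 0 else "frameshift_indel"
    return EffectAnnotation(model.gene_id, category)


def truncated_protein_length(
    model: GeneModel, chrom: str, pos: int, ref: str, alt: str
) -> int:
    """Residues retained by a stopgain variant (complete codons 5' of it).

    A stopgain at 1-based codon k leaves k - 1 residues.  Raises if the
    variant is not a stopgain, or if it replaces the natural stop codon
    (reference protein length unchanged — not a truncation).
    """
    ann = annotate_variant(model, chrom, pos, ref, alt)
    if ann.category != "stopgain":
        raise ValueError(
            f"variant {chrom}:{pos} {ref}>{alt} is {ann.category}, "
            "not stopgain"
        )
    ref_len = len(model.protein())
    assert ann.truncated_length is not None
    if ann.truncated_length >= ref_len:
        raise ValueError("not a truncation: stopgain replaces the natural "
                         "stop codon")
    return ann.truncated_length


def annotate_variants(variants, models: list[GeneModel]):
    """Annotate a variant table against a list of gene models.

    Each variant (frame with ``chrom, pos, ref, alt``) is annotated against
    the gene whose span contains it; variants inside no gene get the nearest
    gene on the chromosome (upstream/downstream) or no annotation if the
    chromosome has no models.  Returns a DataFrame with ``gene_id``,
    ``category``, ``protein_change``, ``truncated_length``, ``distance``.
    """
    import pandas as pd

    by_chrom: dict[str, list[GeneModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chrom, []).append(m)
    rows = []
    for _, v in variants.iterrows():
        chrom, pos = v["chrom"], int(v["pos"])
        ref, alt = str(v["ref"]), str(v["alt"])
        candidates = by_chrom.get(chrom, [])
        chosen = None
        for m in candidates:
            if m.span_start <= pos <= m.span_end:
                chosen = m
                break
        if chosen is None and candidates:
            chosen = min(
                candidates,
                key=lambda m: min(abs(pos - m.span_start),
                                  abs(pos - m.span_end)),
            )
        if chosen is None:
            rows.append((chrom, pos, ref, alt, None, "intergenic",
                         None, None, None))
            continue
        ann = annotate_variant(chosen, chrom, pos, ref, alt)
        rows.append((chrom, pos, ref, alt, ann.gene_id, ann.category,
                     ann.protein_change, ann.truncated_length, ann.distance))
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "gene_id", "category",
                 "protein_change", "truncated_length", "distance"],
    )
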