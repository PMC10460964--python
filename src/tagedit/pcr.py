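"""In-silico PCR: primer-site finding, product prediction, virtual banding.

Amplification is boolean with a "weak" flag when a primer site carries
mismatches; there is no thermodynamic model.  The default binding rule —
at most 2 mismatches with the 3'-terminal base matching exactly — lets a
doubly mismatched primer still produce (weak, nonspecific) products while
a single 3'-terminal mismatch kills the site, mirroring how polymerases
tolerate internal but not 3' mispairing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .model import AlleleArchitecture, TandemArrayModel, revcomp

__all__ = [
    "PrimerPair",
    "BindingRules",
    "PrimerSite",
    "PredictedProduct",
    "find_primer_sites",
    "predict_products",
    "predict_products_genome",
    "predict_banding",
    "BandingReport",
]


@dataclass(frozen=True)
class PrimerPair:
    id: str
    fwd: str
    rev: str
    max_product: int = 3000
    intended_targets: tuple[str, ...] = ()

    def __post_init__(self):
        for p in (self.fwd, self.rev):
            if not 18 <= len(p) <= 30:
                raise ValueError(f"{self.id}: primers must be 18-30 nt")
            if not set(p) <= set("ACGT"):
                raise ValueError(f"{self.id}: primers must be plain ACGT")


@dataclass(frozen=True)
class BindingRules:
    max_mismatches: int = 2
    three_prime_exact: int = 1  # 3'-terminal bases that must match exactly
    min_product: int = 40


@dataclass(frozen=True)
class PrimerSite:
    primer: str  # "fwd" | "rev"
    pos: int     # leftmost axis position of the binding footprint
    strand: str  # "+": primer extends rightward; "-": leftward
    mismatches: int
    mismatch_positions: tuple[int, ...] = ()


def _scan(seq_arr: np.ndarray, primer: str, rules: BindingRules,
          plus_strand: bool) -> list[tuple[int, int, tuple[int, ...]]]:
    """All footprints of ``primer`` on one strand: (pos, n_mm, mm offsets)."""
    m = len(primer)
    probe = primer if plus_strand else revcomp(primer)
    n = len(seq_arr) - m + 1
    if n <= 0:
        return []
    mism = np.zeros(n, dtype=np.int16)
    for j, base in enumerate(probe):
        mism += seq_arr[j:j + n] != ord(base)
    # 3'-terminal exact bases: the right end of the footprint on '+', the
    # left end on '-'
    k = rules.three_prime_exact
    exact = np.zeros(n, dtype=bool) | True
    rng = range(m - k, m) if plus_strand else range(k)
    for j in rng:
        exact &= seq_arr[j:j + n] == ord(probe[j])
    hits = np.nonzero((mism <= rules.max_mismatches) & exact)[0]
    out = []
    for i in hits:
        mm = tuple(int(j) for j in range(m)
                   if seq_arr[i + j] != ord(probe[j])) if mism[i] else ()
        out.append((int(i), int(mism[i]), mm))
    return out


def find_primer_sites(seq: str, primer: str, rules: BindingRules = BindingRules(),
                      label: str = "fwd") -> list[PrimerSite]:
    """All binding sites of one primer on both strands of ``seq``."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    sites = [PrimerSite(label, pos, "+", n, mm)
             for pos, n, mm in _scan(arr, primer, rules, True)]
    sites += [PrimerSite(label, pos, "-", n, mm)
              for pos, n, mm in _scan(arr, primer, rules, False)]
    return sorted(sites, key=lambda s: (s.pos, s.strand))


@dataclass(frozen=True)
class PredictedProduct:
    molecule: str
    start: int
    end: int
    seq: str
    left_site: PrimerSite
    right_site: PrimerSite
    specificity: str  # "specific" | "nonspecific"

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def weak(self) -> bool:
        return self.left_site.mismatches + self.right_site.mismatches > 0


def predict_products(seq: str, pair: PrimerPair,
                     rules: BindingRules = BindingRules(),
                     molecule: str = "seq") -> list[PredictedProduct]:
    """Every convergent site pair within the length cap yields a product.

    All four primer-orientation combinations are considered (single-primer
    products are real PCR artefacts); products are sorted by length.
    """
    plus, minus = [], []
    for label, primer in (("fwd", pair.fwd), ("rev", pair.rev)):
        for s in find_primer_sites(seq, primer, rules, label):
            (plus if s.strand == "+" else minus).append((s, len(primer)))
    products = []
    for ls, lm in plus:
        for rs, rm in minus:
            start, end = ls.pos, rs.pos + rm
            length = end - start
            if rules.min_product <= length <= pair.max_product \
                    and rs.pos >= ls.pos + lm - 5:
                spec = ("specific" if ls.mismatches + rs.mismatches == 0
                        and {ls.primer, rs.primer} == {"fwd", "rev"}
                        else "nonspecific")
                products.append(PredictedProduct(
                    molecule, start, end, seq[start:end], ls, rs, spec))
    return sorted(products, key=lambda p: (p.length, p.start))


def predict_products_genome(genome: dict[str, str], pair: PrimerPair,
                            rules: BindingRules = BindingRules()
                            ) -> list[PredictedProduct]:
    out = []
    for name in sorted(genome):
        out.extend(predict_products(genome[name], pair, rules, molecule=name))
    return sorted(out, key=lambda p: (p.length, p.molecule, p.start))


# ---------------------------------------------------------------------------
# Banding / NA-allele prediction
# ---------------------------------------------------------------------------

@dataclass
class BandingReport:
    line_id: str
    bands: dict[str, list[tuple[int, int]]]      # pair id -> [(length, multiplicity)]
    na_genes: list[str]
    control_ok: bool
    products: dict[str, list[PredictedProduct]] = field(repr=False, default_factory=dict)


def _covered_diag_positions(prod: PredictedProduct,
                            arch: Optional[AlleleArchitecture],
                            array: TandemArrayModel,
                            main_contig: str) -> set[tuple[str, int]]:
    """(contig, axis position) set of reference bases inside a product."""
    covered = set()
    if prod.molecule == main_contig and arch is not None:
        for seg in arch.source_intervals(prod.start, prod.end):
            for p in range(seg.start, seg.end):
                covered.add((seg.contig, p))
    else:
        for p in range(prod.start, prod.end):
            covered.add((prod.molecule, p))
    return covered


def predict_banding(line_id: str, genome: dict[str, str],
                    arch: Optional[AlleleArchitecture],
                    array: TandemArrayModel,
                    panel: Iterable[PrimerPair],
                    rules: BindingRules = BindingRules(),
                    gel_window: tuple[int, int] = (100, 3000),
                    control_locus: str = "c8.1p",
                    main_contig: str = "chr10") -> BandingReport:
    """Banding table plus NA-allele predictions for one line.

    A gene is predicted NA iff no product from any pair contains at least
    one of its diagnostic variant positions (mapped through the line's
    architecture).  The control locus must amplify for NA calls to stand.
    """
    bands: dict[str, list[tuple[int, int]]] = {}
    all_products: dict[str, list[PredictedProduct]] = {}
    covered: set[tuple[str, int]] = set()
    control_ok = False
    control = array.gene(control_locus)
    for pair in panel:
        prods = predict_products_genome(genome, pair, rules)
        all_products[pair.id] = prods
        lengths: dict[int, int] = {}
        for p in prods:
            if gel_window[0] <= p.length <= gel_window[1]:
                lengths[p.length] = lengths.get(p.length, 0) + 1
            covered |= _covered_diag_positions(p, arch, array, main_contig)
            if p.molecule == control.contig \
                    and p.start < control.end and p.end > control.start:
                control_ok = True
        bands[pair.id] = sorted(lengths.items())
    na = []
    for g in array.array_genes():
        diag = array.diagnostic_variants.get(g.id, [])
        hit = any((g.contig, pos) in covered for pos, _ in diag)
        if not hit:
            na.append(g.id)
    return BandingReport(line_id, bands, na, control_ok, all_products)
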