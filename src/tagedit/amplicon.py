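"""Exact-match amplicon read classification and allele calling.

Reads are classified against native + fusion targets with a 0% mismatch
allowance: a read matches a target iff it aligns end-to-end with zero
substitutions and at most one contiguous indel.  This is the right rule for
nearly identical paralogs — a single tolerated substitution would collapse
distinct gene targets — and with error-free reads it is exact string logic.
Read pairs are merged by exact suffix/prefix overlap before matching.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .model import TandemArrayModel, revcomp
from .simulate import ReadPair
from .targets import AmpliconTarget, TargetSet

__all__ = [
    "IndelDescriptor",
    "ReadCall",
    "AlleleCall",
    "NoiseConfig",
    "PopulationSummary",
    "merge_pair",
    "match_read",
    "classify_reads",
    "call_alleles",
    "summarize_population",
]

MIN_MERGE_OVERLAP = 15


@dataclass(frozen=True)
class IndelDescriptor:
    size: int                 # signed; >0 insertion
    offset_from_cut: int      # leftmost-equivalent position minus target cut
    inserted: str = ""

    def key(self) -> tuple:
        return (self.size, self.offset_from_cut, self.inserted)


@dataclass(frozen=True)
class ReadCall:
    read_id: str
    target_ids: tuple[str, ...]
    indel: Optional[IndelDescriptor]
    status: str  # exact | indel | ambiguous | unmatched


@dataclass
class AlleleCall:
    line_id: str
    gene_id: str
    category: str  # native | indel | fusion | na | no_call
    indel: int = 0
    fusion_id: Optional[str] = None
    frame: Optional[str] = None
    fraction: float = 0.0
    count: int = 0
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class NoiseConfig:
    """Variant-retention thresholds; free parameters that a wild-type
    calibration run may override with the maximum observed artifact rate."""

    min_fraction: float = 0.01
    min_count: int = 5


# ---------------------------------------------------------------------------
# Read merging and matching
# ---------------------------------------------------------------------------

def merge_pair(r1: str, r2: str, min_overlap: int = MIN_MERGE_OVERLAP) -> Optional[str]:
    """Merge a read pair by maximal exact suffix/prefix overlap, or None."""
    if not r1 or not r2:
        return None
    tail = revcomp(r2)
    hi = min(len(r1), len(tail))
    for ov in range(hi, min_overlap - 1, -1):
        if r1[-ov:] == tail[:ov]:
            return r1 + tail[ov:]
    return None


def _lcp(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def _lcs(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(1, n + 1):
        if a[-i] != b[-i]:
            return i - 1
    return n


def _align_one_indel(read: str, target: AmpliconTarget) -> Optional[IndelDescriptor]:
    """Zero-substitution alignment with exactly one contiguous indel, or None."""
    t = target.sequence
    d = len(read) - len(t)
    if d == 0:
        return None
    p = _lcp(read, t)
    s = _lcs(read, t)
    short = min(len(read), len(t))
    if p + s < short:
        return None
    if d > 0:
        i = max(0, len(t) - s)
        i = min(i, p)
        return IndelDescriptor(d, i - target.cut, read[i:i + d])
    i = max(0, len(read) - s)
    i = min(i, p)
    return IndelDescriptor(d, i - target.cut)


def match_read(pair: ReadPair, targets: TargetSet,
               min_overlap: int = MIN_MERGE_OVERLAP) -> ReadCall:
    """Classify one read pair against the target set.

    Best match = fewest indels, then smallest |indel|; all tied targets are
    retained (and dedupe ambiguity classes are never split).
    """
    merged = merge_pair(pair.r1, pair.r2, min_overlap)
    if merged is None:
        return ReadCall(pair.read_id, (), None, "unmatched")
    candidates: list[tuple[int, int, AmpliconTarget, Optional[IndelDescriptor]]] = []
    for orient in (merged, revcomp(merged)):
        for t in targets.targets:
            if orient == t.sequence:
                candidates.append((0, 0, t, None))
            else:
                ind = _align_one_indel(orient, t)
                if ind is not None:
                    candidates.append((1, abs(ind.size), t, ind))
        if candidates:
            break  # an orientation that matches wins; avoid double-counting
    if not candidates:
        return ReadCall(pair.read_id, (), None, "unmatched")
    best = min(c[:2] for c in candidates)
    tied = [c for c in candidates if c[:2] == best]
    ids = tuple(sorted({i for _, _, t, _ in tied for i in t.ids}))
    indel = tied[0][3]
    if len(tied) > 1 or len(ids) > 1:
        return ReadCall(pair.read_id, ids, indel, "ambiguous")
    return ReadCall(pair.read_id, ids, indel, "exact" if indel is None else "indel")


def classify_reads(reads: Iterable[ReadPair], targets: TargetSet) -> list[ReadCall]:
    """Vectorized-by-deduplication classification of a read list."""
    cache: dict[tuple[str, str], ReadCall] = {}
    out = []
    for pair in reads:
        key = (pair.r1, pair.r2)
        hit = cache.get(key)
        if hit is None:
            hit = match_read(pair, targets)
            cache[key] = hit
        out.append(ReadCall(pair.read_id, hit.target_ids, hit.indel, hit.status))
    return out


# ---------------------------------------------------------------------------
# Allele calling
# ---------------------------------------------------------------------------

def _components(target_id: str, targets: TargetSet) -> tuple[str, ...]:
    try:
        t = targets.get(target_id)
    except KeyError:
        return (target_id,)
    # the id's own composition, not the class representative's
    if "-" in target_id and len(t.components) == 2:
        return tuple(target_id.split("-", 1))
    if target_id in t.ids and target_id == t.id:
        return t.components
    return tuple(target_id.split("-", 1)) if "-" in target_id else (target_id,)


def call_alleles(line_id: str, read_calls: list[ReadCall], targets: TargetSet,
                 array: TandemArrayModel, noise: NoiseConfig = NoiseConfig(),
                 control_locus: str = "c8.1p",
                 gene_ids: Optional[list[str]] = None
                 ) -> tuple[list[AlleleCall], bool]:
    """Per-gene allele calls for one line.

    Variants survive if their read fraction and count clear the noise
    thresholds.  Genes with zero surviving attributable reads are NA iff
    the nontarget control locus amplified (guards against PCR failure);
    otherwise the whole run is flagged and no NA calls are made.
    """
    gene_ids = gene_ids or [g.id for g in array.array_genes()]
    total = max(len(read_calls), 1)

    variants: Counter = Counter()
    for rc in read_calls:
        if rc.status == "unmatched":
            continue
        key = (rc.target_ids, rc.indel.key() if rc.indel else None,
               rc.status == "ambiguous")
        variants[key] += 1

    kept = [(ids, indel_key, amb, n) for (ids, indel_key, amb), n in variants.items()
            if n >= noise.min_count and n / total >= noise.min_fraction]

    control_reads = sum(n for ids, _, _, n in kept if control_locus in ids)
    run_ok = control_reads >= noise.min_count

    per_gene: dict[str, list[tuple]] = {g: [] for g in gene_ids}
    for ids, indel_key, amb, n in kept:
        touched: set[str] = set()
        for tid in ids:
            for comp in _components(tid, targets):
                if comp in per_gene:
                    touched.add(comp)
        for g in touched:
            per_gene[g].append((ids, indel_key, amb, n))

    calls: list[AlleleCall] = []
    for g in gene_ids:
        hits = sorted(per_gene[g], key=lambda v: -v[3])
        if not hits:
            cat = "na" if run_ok else "no_call"
            calls.append(AlleleCall(line_id, g, cat))
            continue
        ids, indel_key, amb, n = hits[0]
        flags = []
        if amb or len(ids) > 1:
            flags.append("ambiguous")
        if len(hits) > 1:
            flags.append("conflict")
        size = indel_key[0] if indel_key else 0
        primary = ids[0]
        comp = _components(primary, targets)
        if len(comp) == 2:
            cut_in_cds = all(array.gene(c).in_cds(array.gene(c).cut_point)
                             for c in comp if not array.gene(c).is_pseudogene)
            frame = ("in_frame" if size % 3 == 0 else "frameshift") \
                if cut_in_cds else "noncoding"
            calls.append(AlleleCall(line_id, g, "fusion", size, primary, frame,
                                    n / total, n, tuple(flags)))
        elif size:
            calls.append(AlleleCall(line_id, g, "indel", size, None, None,
                                    n / total, n, tuple(flags)))
        else:
            calls.append(AlleleCall(line_id, g, "native", 0, None, None,
                                    n / total, n, tuple(flags)))
    return calls, run_ok


# ---------------------------------------------------------------------------
# Population summary
# ---------------------------------------------------------------------------

@dataclass
class PopulationSummary:
    n_lines: int
    n_genes: int
    sites_total: int
    counts: dict[str, int]
    percentages: dict[str, int]          # nearest-integer percent of sites
    indel_histogram: dict[int, int]
    n_fusion_alleles: int
    fusion_adjacent: int
    fusion_nonadjacent: int

    def to_dict(self) -> dict:
        return {
            "n_lines": self.n_lines,
            "n_genes": self.n_genes,
            "sites_total": self.sites_total,
            "counts": dict(self.counts),
            "percentages": dict(self.percentages),
            "indel_histogram": {str(k): v for k, v in
                                sorted(self.indel_histogram.items())},
            "n_fusion_alleles": self.n_fusion_alleles,
            "fusion_adjacent": self.fusion_adjacent,
            "fusion_nonadjacent": self.fusion_nonadjacent,
        }


def summarize_population(calls: list[AlleleCall],
                         array: Optional[TandemArrayModel] = None
                         ) -> PopulationSummary:
    """Category counts/percentages and indel spectrum across a population.

    Total sites = lines x genes; a fusion occupies the cells of both
    partner genes (a linked pair) and the genes lost to its dropout count
    as NA.  Percentages are rounded to the nearest integer.
    """
    lines = sorted({c.line_id for c in calls})
    genes = sorted({c.gene_id for c in calls})
    sites = len(lines) * len(genes)
    counts = Counter(c.category for c in calls)
    for cat in ("native", "indel", "fusion", "na", "no_call"):
        counts.setdefault(cat, 0)
    pct = {cat: round(100 * n / sites) if sites else 0
           for cat, n in counts.items()}

    hist: Counter = Counter()
    seen_fusions = set()
    for c in calls:
        if c.category == "indel":
            hist[c.indel] += 1
        elif c.category == "fusion" and c.indel:
            # a fusion allele occupies both partner cells: count its net once
            key = (c.line_id, c.fusion_id)
            if key not in seen_fusions:
                seen_fusions.add(key)
                hist[c.indel] += 1

    fusions = {(c.line_id, c.fusion_id) for c in calls
               if c.category == "fusion" and c.fusion_id}
    if array is not None:
        idx = {g.id: i for i, g in enumerate(array.array_genes())}
    else:
        idx = {g: i for i, g in enumerate(genes)}
    adj = nonadj = 0
    for _, fid in fusions:
        a, b = fid.split("-", 1)
        if a in idx and b in idx:
            if abs(idx[a] - idx[b]) == 1:
                adj += 1
            else:
                nonadj += 1
    return PopulationSummary(len(lines), len(genes), sites, dict(counts), pct,
                             dict(hist), len(fusions), adj, nonadj)
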