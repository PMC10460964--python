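"""Capture-read mapping, coverage, discordant pairs, and junction assembly.

The mapper is a desk-scale k-mer seed-and-extend aligner (k = 15) with the
"first best" tie rule: each read end is placed at its best exact-extension
location, and among tied best locations the first in (contig order,
position) wins — deterministic, which matters when paralogs are
near-identical.  It is not a general-purpose aligner: no soft-clipping
semantics, no base qualities.

Structural signal comes from three layers: per-window coverage (dropouts),
discordant read-pair orientation/distance clusters (inversions,
translocations, large deletions), and greedy exact-overlap assembly of
cluster reads into junction contigs that are segmented against the
references by maximal exact-match switching.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np

from .model import (
    AlleleArchitecture,
    InlineEdit,
    Junction,
    Segment,
    TandemArrayModel,
    junction_set,
    render_sequence,
    revcomp,
)
from .simulate import ReadPair

__all__ = [
    "ReferenceIndex",
    "EndAlignment",
    "PairAlignment",
    "DiscordantCluster",
    "DropoutCall",
    "map_reads",
    "coverage_profile",
    "detect_dropouts",
    "detect_discordant",
    "assemble_junction",
    "segment_junction",
    "read_vote_junctions",
    "greedy_assemble",
    "gene_mean_depth",
    "collect_capture_evidence",
    "CaptureEvidence",
]

DEFAULT_K = 15


class ReferenceIndex:
    """Exact k-mer index over the reference contigs (plus strand)."""

    def __init__(self, contigs: dict[str, str], k: int = DEFAULT_K):
        self.k = k
        self.names = list(contigs)
        self.seqs = [contigs[n] for n in self.names]
        self.index: dict[str, list[tuple[int, int]]] = {}
        for ci, seq in enumerate(self.seqs):
            for i in range(len(seq) - k + 1):
                self.index.setdefault(seq[i:i + k], []).append((ci, i))

    def lookup(self, kmer: str) -> list[tuple[int, int]]:
        return self.index.get(kmer, [])


@dataclass(frozen=True)
class EndAlignment:
    contig: str
    start: int
    end: int
    strand: str
    score: int
    exact: bool


@dataclass(frozen=True)
class PairAlignment:
    pair_id: str
    end1: Optional[EndAlignment]
    end2: Optional[EndAlignment]
    orientation: str


def _match_count(a: bytes, b: bytes) -> int:
    if a == b:
        return len(a)
    x = np.frombuffer(a, dtype=np.uint8)
    y = np.frombuffer(b, dtype=np.uint8)
    n = min(len(x), len(y))
    return int((x[:n] == y[:n]).sum())


def _map_end_candidates(read: str, ref: ReferenceIndex
                        ) -> list[EndAlignment]:
    """All tied-best placements of one end, in (contig, position) order."""
    k = ref.k
    L = len(read)
    if L < k:
        raise ValueError("k-mer length exceeds read length")
    offsets = sorted({0, (L - k) // 2, L - k})
    candidates: set[tuple[int, int, str]] = set()
    for strand, rseq in (("+", read), ("-", revcomp(read))):
        for off in offsets:
            for ci, pos in ref.lookup(rseq[off:off + k]):
                start = pos - off
                if 0 <= start and start + L <= len(ref.seqs[ci]):
                    candidates.add((ci, start, strand))
    scored = []
    for ci, start, strand in sorted(candidates):
        rseq = read if strand == "+" else revcomp(read)
        score = _match_count(rseq.encode(),
                             ref.seqs[ci][start:start + L].encode())
        scored.append((-score, ci, start, strand))
    if not scored:
        return []
    scored.sort()
    best = scored[0][0]
    return [EndAlignment(ref.names[ci], start, start + L, strand, -s, -s == L)
            for s, ci, start, strand in scored if s == best]


def _map_end(read: str, ref: ReferenceIndex) -> Optional[EndAlignment]:
    cands = _map_end_candidates(read, ref)
    return cands[0] if cands else None


def _classify(e1: Optional[EndAlignment], e2: Optional[EndAlignment],
              insert_lo: int, insert_hi: int) -> str:
    if e1 is None or e2 is None:
        return "one_end_unmapped"
    if e1.contig != e2.contig:
        return "interchrom"
    if e1.strand == e2.strand:
        return "FF" if e1.strand == "+" else "RR"
    plus = e1 if e1.strand == "+" else e2
    minus = e2 if plus is e1 else e1
    if plus.start <= minus.end:
        span = minus.end - plus.start
        return "FR_proper" if insert_lo <= span <= insert_hi else "long_insert"
    return "RF_outward"


def map_reads(pairs: Iterable[ReadPair], ref: ReferenceIndex,
              insert_mean: float = 550.0, insert_sd: float = 60.0
              ) -> list[PairAlignment]:
    """Map read pairs; orientation class uses mean +/- 4 sd insert bounds.

    Each end is placed first-best, but when the first-best pair looks
    discordant and some other tied-best combination of placements is a
    proper pair, that combination wins (pair rescue).  Near-identical
    paralogs tie constantly; without rescue, ties systematically fake
    discordance.
    """
    lo = max(0, int(insert_mean - 4 * insert_sd))
    hi = int(insert_mean + 4 * insert_sd)
    out = []
    for p in pairs:
        c1 = _map_end_candidates(p.r1, ref)
        c2 = _map_end_candidates(p.r2, ref)
        e1 = c1[0] if c1 else None
        e2 = c2[0] if c2 else None
        cls = _classify(e1, e2, lo, hi)
        if cls not in ("FR_proper", "one_end_unmapped") and len(c1) * len(c2) > 1:
            best = None  # (not proper, not same contig, span, a, b)
            for a in c1:
                for b in c2:
                    k = _classify(a, b, lo, hi)
                    same = a.contig == b.contig
                    span = abs(((a.start + a.end) - (b.start + b.end)) // 2) \
                        if same else 1 << 30
                    key = (k != "FR_proper", not same, span)
                    if best is None or key < best[0]:
                        best = (key, a, b, k)
            _, e1, e2, cls = best
        out.append(PairAlignment(p.read_id, e1, e2, cls))
    return out


# ---------------------------------------------------------------------------
# Coverage and dropouts
# ---------------------------------------------------------------------------

def coverage_profile(alignments: Iterable[PairAlignment],
                     array: TandemArrayModel, window: int = 200
                     ) -> dict[str, np.ndarray]:
    """Per-window mean depth per contig (diff-array accumulation)."""
    depth = {name: np.zeros(len(seq) + 1)
             for name, seq in array.contigs.items()}
    for pa in alignments:
        for e in (pa.end1, pa.end2):
            if e is not None:
                depth[e.contig][e.start] += 1
                depth[e.contig][e.end] -= 1
    out = {}
    for name, d in depth.items():
        per_base = np.cumsum(d[:-1])
        n_win = (len(per_base) + window - 1) // window
        padded = np.zeros(n_win * window)
        padded[:len(per_base)] = per_base
        out[name] = padded.reshape(n_win, window).mean(axis=1)
    return out


def gene_mean_depth(profile: dict[str, np.ndarray], array: TandemArrayModel,
                    window: int = 200) -> dict[str, float]:
    out = {}
    for g in array.genes:
        wins = profile[g.contig][g.start // window:(g.end + window - 1) // window]
        out[g.id] = float(wins.mean()) if len(wins) else 0.0
    return out


@dataclass(frozen=True)
class DropoutCall:
    contig: str
    start: int
    end: int
    genes: tuple[str, ...]
    flanking_cuts: tuple[Optional[int], Optional[int]]


def detect_dropouts(profile: dict[str, np.ndarray], array: TandemArrayModel,
                    window: int = 200, threshold_frac: float = 0.1,
                    main_contig: str = "chr10",
                    min_windows: int = 3) -> list[DropoutCall]:
    """Maximal runs of sub-threshold gene windows, trimmed to gene bodies.

    The per-line reference depth is the 90th percentile of gene-body window
    depths (robust when most of the array has dropped out); the threshold
    is ``threshold_frac`` of it.  Only probe-homologous (gene-body) windows
    are tested — intergenic sequence is not captured and carries no signal.
    """
    prof = profile[main_contig]
    genes = [g for g in array.genes_on(main_contig) if not g.is_pseudogene]
    win_ids: list[tuple[int, str]] = []
    for g in genes:
        for w in range(g.start // window, (g.end + window - 1) // window):
            win_ids.append((w, g.id))
    depths = np.array([prof[w] for w, _ in win_ids])
    if not len(depths):
        return []
    ref_depth = float(np.percentile(depths, 90))
    # anchor on the nontarget pseudogene loci (capture's built-in control):
    # when most or all of the array has dropped out, the gene windows alone
    # cannot define a per-line reference depth
    pseudo = []
    for g in array.pseudogenes():
        pw = profile[g.contig][g.start // window:
                               (g.end + window - 1) // window]
        pseudo.extend(float(x) for x in pw)
    if pseudo:
        ref_depth = max(ref_depth, float(np.median(pseudo)))
    thr = threshold_frac * ref_depth
    low = depths < thr

    calls = []
    i = 0
    cuts = sorted(g.cut_point for g in genes)
    while i < len(win_ids):
        if not low[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(win_ids) and low[j + 1]:
            j += 1
        if j - i + 1 < min_windows:
            i = j + 1
            continue
        start = win_ids[i][0] * window
        end = (win_ids[j][0] + 1) * window
        hit_genes = tuple(sorted({gid for k, (w, gid) in enumerate(win_ids)
                                  if i <= k <= j}))
        left = max((c for c in cuts if c <= start), default=None)
        right = min((c for c in cuts if c >= end), default=None)
        calls.append(DropoutCall(main_contig, start, end, hit_genes,
                                 (left, right)))
        i = j + 1

    # mis-mapped paralog reads can leave a one- or two-window blip inside a
    # real dropout: merge calls separated by <= 2 gene windows
    merged: list[DropoutCall] = []
    for c in calls:
        if merged and c.start - merged[-1].end <= 2 * window \
                and c.contig == merged[-1].contig:
            prev = merged.pop()
            left = max((x for x in cuts if x <= prev.start), default=None)
            right = min((x for x in cuts if x >= c.end), default=None)
            merged.append(DropoutCall(
                c.contig, prev.start, c.end,
                tuple(sorted(set(prev.genes) | set(c.genes))), (left, right)))
        else:
            merged.append(c)
    return merged


# ---------------------------------------------------------------------------
# Discordant pairs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiscordantCluster:
    orientation: str
    left_contig: str
    left_span: tuple[int, int]
    right_contig: str
    right_span: tuple[int, int]
    support: int
    pair_ids: tuple[str, ...]
    loci: tuple[str, ...]
    loci_left: tuple[str, ...] = ()
    loci_right: tuple[str, ...] = ()


DISCORDANT_CLASSES = ("FF", "RR", "RF_outward", "long_insert", "interchrom")


def detect_discordant(alignments: Iterable[PairAlignment],
                      array: TandemArrayModel, insert_mean: float = 550.0,
                      min_support: int = 3) -> list[DiscordantCluster]:
    """Cluster discordant pairs by orientation class and end proximity."""
    by_class: dict[str, list[PairAlignment]] = {}
    for pa in alignments:
        if pa.orientation in DISCORDANT_CLASSES:
            by_class.setdefault(pa.orientation, []).append(pa)

    def keyed(pa: PairAlignment):
        ends = sorted([pa.end1, pa.end2],
                      key=lambda e: (e.contig, e.start))
        return ends[0], ends[1]

    clusters = []
    gap = insert_mean
    for cls, members in sorted(by_class.items()):
        members.sort(key=lambda pa: (keyed(pa)[0].contig, keyed(pa)[0].start,
                                     keyed(pa)[1].contig, keyed(pa)[1].start))
        group: list[PairAlignment] = []
        prev = None
        for pa in members + [None]:
            if pa is not None:
                l, r = keyed(pa)
            newgrp = (pa is None or prev is None
                      or l.contig != prev[0].contig
                      or r.contig != prev[1].contig
                      or l.start - prev[0].start > gap
                      or abs(r.start - prev[1].start) > gap)
            if newgrp and group:
                clusters.append(_make_cluster(cls, group, array, insert_mean))
                group = []
            if pa is not None:
                group.append(pa)
                prev = (l, r)
        # trailing group flushed by the None sentinel above
    return [c for c in clusters if c.support >= min_support]


def _make_cluster(cls: str, group: list[PairAlignment],
                  array: TandemArrayModel, insert_mean: float
                  ) -> DiscordantCluster:
    lefts, rights = [], []
    for pa in group:
        ends = sorted([pa.end1, pa.end2], key=lambda e: (e.contig, e.start))
        lefts.append(ends[0])
        rights.append(ends[1])
    lc, rc = lefts[0].contig, rights[0].contig
    lspan = (min(e.start for e in lefts), max(e.end for e in lefts))
    rspan = (min(e.start for e in rights), max(e.end for e in rights))
    def span_loci(contig, span):
        return tuple(sorted(
            g.id for g in array.genes_on(contig)
            if g.start < span[1] + insert_mean and g.end > span[0] - insert_mean))

    left = span_loci(lc, lspan)
    right = span_loci(rc, rspan)
    return DiscordantCluster(cls, lc, lspan, rc, rspan, len(group),
                             tuple(pa.pair_id for pa in group),
                             tuple(sorted(set(left) | set(right))),
                             left, right)


# ---------------------------------------------------------------------------
# Junction assembly
# ---------------------------------------------------------------------------

def _best_overlap(a: str, b: str, min_overlap: int) -> int:
    """Largest exact suffix(a)/prefix(b) overlap >= min_overlap, seeded on
    b's prefix so mismatching pairs cost one substring search."""
    seed = b[:min_overlap]
    lo = len(a) - min(len(a), len(b))
    pos = a.find(seed, lo)
    while pos != -1:
        ov = len(a) - pos
        if a[pos:] == b[:ov]:
            return ov
        pos = a.find(seed, pos + 1)
    return 0


def greedy_assemble(reads: list[str], min_overlap: int = 40,
                    max_contig: int = 1500) -> list[str]:
    """Greedy exact suffix/prefix overlap assembly (error-free reads).

    Both read orientations enter the pool and assemble in parallel, so the
    junction contig and its reverse complement both emerge; merges are
    capped at ``max_contig`` so inverted-repeat joints cannot self-extend
    without bound.
    """
    frags = sorted(set(reads) | {revcomp(r) for r in reads})
    frags = [f for f in frags if f]
    # drop fragments fully contained in another
    frags = [f for f in frags
             if not any(f != g and f in g for g in frags)]
    for _ in range(4 * len(frags) + 8):
        best = None
        n = len(frags)
        for i in range(n):
            for j in range(n):
                if i == j or len(frags[i]) + len(frags[j]) > max_contig:
                    continue
                ov = _best_overlap(frags[i], frags[j], min_overlap)
                if ov and (best is None or ov > best[0]):
                    best = (ov, i, j)
        if best is None:
            break
        ov, i, j = best
        merged = frags[i] + frags[j][ov:]
        frags = [f for k, f in enumerate(frags) if k not in (i, j)
                 and f not in merged]
        frags.append(merged)
    return sorted(frags, key=len, reverse=True)


def _extend_from_anchor(contig_seq: str, ref_seq: str, cpos: int, rpos: int,
                        k: int) -> tuple[int, int]:
    """Maximal exact extension of an anchored k-mer match; returns the
    (left extension, right extension) beyond the anchor in contig coords."""
    left = 0
    while cpos - left - 1 >= 0 and rpos - left - 1 >= 0 \
            and contig_seq[cpos - left - 1] == ref_seq[rpos - left - 1]:
        left += 1
    right = 0
    while cpos + k + right < len(contig_seq) and rpos + k + right < len(ref_seq) \
            and contig_seq[cpos + k + right] == ref_seq[rpos + k + right]:
        right += 1
    return left, right


def _anchor_matches(contig: str, cpos: int, ref: ReferenceIndex
                    ) -> list[tuple[int, str, int, int, int]]:
    """All maximal exact matches through the k-mer at contig offset ``cpos``:
    (match length, source contig, src start, strand, contig match start)."""
    k = ref.k
    out = []
    kmer = contig[cpos:cpos + k]
    for ci, pos in ref.lookup(kmer):
        left, right = _extend_from_anchor(contig, ref.seqs[ci], cpos, pos, k)
        out.append((k + left + right, ref.names[ci], pos - left, "+",
                    cpos - left))
    rc = revcomp(contig)
    rpos = len(contig) - cpos - k
    for ci, pos in ref.lookup(rc[rpos:rpos + k]):
        left, right = _extend_from_anchor(rc, ref.seqs[ci], rpos, pos, k)
        mstart_rc = rpos - left
        mlen = k + left + right
        out.append((mlen, ref.names[ci], pos - left, "-",
                    len(contig) - (mstart_rc + mlen)))
    return sorted(out, key=lambda t: (-t[0], t[1], t[2]))


def _locate_insert(seq: str, ref: ReferenceIndex,
                   array: TandemArrayModel) -> Optional[tuple[str, int, int]]:
    """Exact location of an inserted block in the references -> templated
    insert source (locus id, t offset, length), or None."""
    for probe in (seq, revcomp(seq)):
        for ci, ref_seq in enumerate(ref.seqs):
            p = ref_seq.find(probe)
            if p >= 0:
                locus, t = array.locus_at(ref.names[ci], p)
                if locus.strand == "-":
                    t = locus.axis_to_t(p + len(seq))
                return (locus.id, t, len(seq))
    return None


def _single_indel_same_source(seq: str, ref: ReferenceIndex, lm,
                              max_indel: int = 25) -> bool:
    """True when ``seq`` equals the left match's own reference continuation
    with exactly one small contiguous indel."""
    mlen, contig, start, strand, _ = lm
    ci = ref.names.index(contig)
    R = ref.seqs[ci]
    if strand == "+":
        region = R[start:start + len(seq) + max_indel + 5]
    else:
        end = start + mlen
        lo = max(0, end - len(seq) - max_indel - 5)
        region = revcomp(R[lo:end])
    tail = seq[mlen:]
    if not tail:
        return True
    base = region[mlen:]
    for d in range(1, max_indel + 1):
        if base[d:d + len(tail)] == tail:        # deletion of d in seq source
            return True
        if len(tail) > d and base[:len(tail) - d] == tail[d:]:  # insertion
            return True
    return False


def _segment_combo(seq, ref, array, min_segment, provenance,
                   lm, rm, validate):
    """Evaluate one (left anchor, right anchor) combination; see
    _segment_arch."""
    mlen_l, lc, lstart, lstrand, _ = lm
    mlen_r, rcg, rstart, rstrand, rseq_start = rm
    if mlen_l < min_segment or mlen_r < min_segment:
        return None
    m1 = mlen_l                       # offset where the left match ends
    m2 = rseq_start                   # offset where the right match starts
    if m1 >= m2 + mlen_r:             # single source; no switch
        return None
    inserted = seq[m1:m2] if m2 > m1 else ""
    micro = m1 - m2 if m2 < m1 else 0  # microhomology assigned to the left
    if lstrand == "+":
        seg_l = Segment(lc, lstart, lstart + m1, "+")
    else:
        lend = lstart + mlen_l
        seg_l = Segment(lc, lend - m1, lend, "-")
    # the right segment keeps >= 12 bp beyond the microhomology; its locus
    # identity rests on the full match length, so the post-micro remnant
    # only needs to be positive with margin
    rlen = mlen_r - micro
    if rlen < 12:
        return None
    if rstrand == "+":
        seg_r = Segment(rcg, rstart + micro, rstart + mlen_r, "+")
    else:
        seg_r = Segment(rcg, rstart, rstart + rlen, "-")
    if (seg_l.contig == seg_r.contig and seg_l.orient == seg_r.orient
            and (seg_l.end == seg_r.start if seg_l.orient == "+"
                 else seg_r.end == seg_l.start)):
        return None  # reference-adjacent: not a junction
    edits = []
    if inserted:
        src = _locate_insert(inserted, ref, array)
        bpos = seg_r.start if seg_r.orient == "+" else seg_r.end
        edits.append(InlineEdit(seg_r.contig, bpos, len(inserted),
                                inserted, src))
    arch = AlleleArchitecture([seg_l, seg_r], edits)
    juncs = junction_set(arch, array, provenance=provenance)
    if not juncs:
        return None
    j0 = juncs[0]
    if inserted and edits and edits[0].insert_source is not None:
        # an "insert" copied from right next to one of the joint's own sides
        # is that gene's own continuation (a misread small indel), not a
        # templated insert from a distant donor
        sl, st, sn = edits[0].insert_source
        for gid, t in (j0.side5, j0.side3):
            if gid == sl and min(abs(st - t), abs(st + sn - t)) <= 50:
                return None
    if j0.orientation == "opposing" and j0.side5[0] == j0.side3[0]:
        # a same-locus foldback joint is outside the event model; with
        # near-palindromic inversion joints it is always a misassignment
        return None
    if j0.orientation == "productive" and j0.side5[0] != j0.side3[0] \
            and abs(j0.net_indel) <= 25:
        # a small indel in one paralog makes the wrong paralog's reference
        # extend further past the indel; if one source plus one indel
        # explains the whole sequence, this is not a fusion
        mlen_r_, rc_, rstart_, rstrand_, _ = rm
        rm_as_lm = (mlen_r_, rc_, rstart_,
                    "-" if rstrand_ == "+" else "+", 0)
        if _single_indel_same_source(seq, ref, lm) or \
                _single_indel_same_source(revcomp(seq), ref, rm_as_lm):
            return None
    if not validate:
        return arch, juncs[0], []
    # validation for assembled contigs: the window spanning the whole
    # joint-ambiguity (microhomology) region plus flanks reaching
    # locus-specific sequence must (a) not occur in the references — else it
    # is a conserved native stretch, not a joint — and (b) be attested by a
    # sequenced read (half-windows for long templated inserts): greedy
    # assembly can chain two intact paralogs through an identical overlap,
    # faking a novel joint no read ever saw
    ins = len(inserted)
    w = 35
    rendered = render_sequence(arch, array)
    m1r = seg_l.length
    lo = max(0, m1r - micro - w)
    hi = min(len(rendered), m1r + ins + w)
    if m1r - micro - lo < 10 or hi - (m1r + ins) < 10:
        return None
    window = rendered[lo:hi]
    for s in ref.seqs:
        if window in s or revcomp(window) in s:
            return None
    if hi - lo <= 140:
        parts = [window]
    elif ins >= 15:
        # a templated insert is novel content: each edge (flank + insert
        # margin) is independently attestable and cannot be native
        micro_start = m1r - micro
        parts = [rendered[lo:micro_start + 15],
                 rendered[max(lo, m1r + ins - 15):hi]]
    else:
        # long microhomology without an insert: the half-windows would be
        # near-native and attestable by reads from intact paralogs, which is
        # exactly how a misassigned small indel fakes a fusion — reject and
        # leave the cluster gray (read votes handle these joints)
        return None
    return arch, juncs[0], parts


def _segment_arch(seq: str, ref: ReferenceIndex, array: TandemArrayModel,
                  min_segment: int, provenance: str, validate: bool = False,
                  want_orientation: Optional[str] = None,
                  preferred_loci=None
                  ) -> Optional[tuple[AlleleArchitecture, Junction, list[str]]]:
    """Segment one sequence against the references by maximal exact-match
    switching; return the junction at the switch point, if any.

    The sequence is anchored at both ends by maximal exact matches; when
    the two matches come from non-adjacent reference positions the switch
    is a junction.  An unmatched middle block is recorded as inserted
    sequence with its templated source when it locates exactly in the
    references.  Microhomology at the joint is assigned leftmost
    (5'-equivalent) — the joint is placed where the left match ends.
    Matches shorter than ``min_segment`` abstain: with near-identical
    paralogs a short match cannot name its source locus reliably.

    Without ``want_orientation`` (single-read evidence) only the top anchor
    pair is used and equal-length anchor ties abstain.  With it (assembled
    contigs, where read-pair geometry fixes the expected joint orientation)
    anchor combinations are tried best-first and the first validated
    junction of the wanted orientation wins.
    """
    k = ref.k
    if len(seq) < 2 * k + min_segment:
        return None
    lmatches = [m for m in _anchor_matches(seq, 0, ref) if m[4] == 0]
    rmatches = [m for m in _anchor_matches(seq, len(seq) - k, ref)
                if m[4] + m[0] == len(seq)]
    if not lmatches or not rmatches:
        return None
    if want_orientation is None:
        # a flank whose best match ties between two reference placements
        # cannot name its source paralog: abstain rather than guess
        if len(lmatches) > 1 and lmatches[1][0] == lmatches[0][0]:
            return None
        if len(rmatches) > 1 and rmatches[1][0] == rmatches[0][0]:
            return None
        return _segment_combo(seq, ref, array, min_segment, provenance,
                              lmatches[0], rmatches[0], validate)
    # the wanted orientation constrains the anchor strand pair; ties are
    # still abstained from within each strand class
    allowed = {"productive": (("+", "+"), ("-", "-")),
               "opposing": (("+", "-"), ("-", "+"))}[want_orientation]
    combos = []
    for sl, sr in allowed:
        lms = [m for m in lmatches if m[3] == sl]
        rms = [m for m in rmatches if m[3] == sr]
        if not lms or not rms:
            continue
        if len(lms) > 1 and lms[1][0] == lms[0][0]:
            continue
        if len(rms) > 1 and rms[1][0] == rms[0][0]:
            continue
        combos.append((lms[0], rms[0]))
    combos.sort(key=lambda c: (-(c[0][0] + c[1][0]), c[0][1:], c[1][1:]))
    validated = []
    for lm, rm in combos:
        got = _segment_combo(seq, ref, array, min_segment, provenance,
                             lm, rm, validate)
        if got is not None and got[1].orientation == want_orientation:
            validated.append(got)
    if not validated:
        return None
    if preferred_loci:
        # soft preference: in near-palindromic joint neighbourhoods several
        # locus assignments validate; the pair-cluster hull breaks the tie
        for got in validated:
            j = got[1]
            if {j.side5[0], j.side3[0]} <= set(preferred_loci):
                return got
    return validated[0]


def segment_junction(seq: str, ref: ReferenceIndex, array: TandemArrayModel,
                     min_segment: int = 50,
                     provenance: str = "contig") -> Optional[Junction]:
    got = _segment_arch(seq, ref, array, min_segment, provenance)
    return got[1] if got else None


CLUSTER_ORIENTATION_PRIOR = {
    "FF": "opposing", "RR": "opposing",
    "long_insert": "productive", "RF_outward": "productive",
}


def assemble_junction(reads: list[str], ref: ReferenceIndex,
                      array: TandemArrayModel, min_overlap: int = 40,
                      min_segment: int = 60,
                      want_orientation: Optional[str] = None,
                      preferred_loci=None) -> Optional[Junction]:
    """Assemble reads near a cluster and segment the contigs against the
    references; return the first junction that passes validation.

    ``want_orientation`` carries the read-pair geometry prior (FF/RR
    clusters imply an opposing joint); it disambiguates anchor matches in
    near-palindromic joint neighbourhoods.  Greedy assembly can also chain
    reads from two intact paralogs through a paralog-identical overlap,
    faking a novel joint; a real joint window must therefore occur verbatim
    inside at least one input read.
    """
    for contig in greedy_assemble(reads, min_overlap):
        got = _segment_arch(contig, ref, array, min_segment, "contig",
                            validate=True, want_orientation=want_orientation,
                            preferred_loci=preferred_loci)
        if got is None:
            continue
        _, junction, parts = got
        if all(any(p in r or revcomp(p) in r for r in reads) for p in parts):
            return junction
    return None


def read_vote_junctions(reads: list[ReadPair],
                        alignments: list[PairAlignment],
                        ref: ReferenceIndex, array: TandemArrayModel,
                        min_votes: int = 3, min_segment: int = 50
                        ) -> tuple[list[tuple[Junction, int]], list[Junction]]:
    """Junction discovery from individual junction-spanning reads.

    A read that crosses a joint cannot map exactly, so every inexactly
    mapped end is segmented against the references; junctions are accepted
    at ``min_votes`` independent read votes (majority voting suppresses
    misassignment from paralog-identical stretches).  Returns (structural
    junctions, small-indel joints).
    """
    by_id = {p.read_id: p for p in reads}
    votes: dict[tuple, list[Junction]] = {}
    for pa in alignments:
        p = by_id.get(pa.pair_id)
        if p is None:
            continue
        for e, seq in ((pa.end1, p.r1), (pa.end2, p.r2)):
            if e is not None and e.exact:
                continue
            j = segment_junction(seq, ref, array, min_segment, "read_pair")
            if j is not None:
                votes.setdefault(j.signature(), []).append(j)
    structural, indels = [], []
    for sig, members in sorted(votes.items()):
        if len(members) < min_votes:
            continue
        best = max(members, key=lambda j: len(j.inserted))
        if _is_small_indel_joint(best):
            indels.append(best)
        else:
            # one signature can cover two physical joints (an inversion's
            # two breakpoints): keep the union of claimed portions
            ports = tuple(sorted({p for m in members for p in m.portions}))
            structural.append((replace(best, portions=ports), len(members)))
    return structural, indels


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class CaptureEvidence:
    alignments: list[PairAlignment] = field(repr=False, default_factory=list)
    profile: dict = field(repr=False, default_factory=dict)
    gene_depth: dict[str, float] = field(default_factory=dict)
    dropouts: list[DropoutCall] = field(default_factory=list)
    clusters: list[DiscordantCluster] = field(default_factory=list)
    junctions: list[Junction] = field(default_factory=list)
    indel_evidence: list[Junction] = field(default_factory=list)
    unassembled: list[DiscordantCluster] = field(default_factory=list)


def _expanded_portions(j: Junction) -> tuple:
    """An opposing signature stands for an inversion's two physical joints,
    which together claim both the head and tail of each side locus."""
    ports = set(j.portions)
    if j.orientation == "opposing":
        for locus, kind, t in j.portions:
            ports.add((locus, "head" if kind == "tail" else "tail", t))
    return tuple(sorted(ports))


def _portion_conflict(a: Junction, b: Junction) -> bool:
    """Two distinct junctions claim overlapping transcript intervals of one
    locus (head = [0,t), tail = [t,L)): impossible on a single haplotype."""
    if a.signature() == b.signature():
        return False
    for l1, k1, t1 in _expanded_portions(a):
        for l2, k2, t2 in _expanded_portions(b):
            if l1 != l2:
                continue
            if k1 == k2:
                return True
            th = t1 if k1 == "head" else t2
            tt = t2 if k1 == "head" else t1
            if th > tt:
                return True
    return False


def synthesize_templated_junctions(voted: list[tuple[Junction, int]],
                                   array: TandemArrayModel,
                                   ref: ReferenceIndex,
                                   reads: list[ReadPair],
                                   max_insert: int = 200
                                   ) -> list[tuple[Junction, int]]:
    """Reconstruct three-way (templated-insert) joints from their edge views.

    A read can cross only one edge of an inserted block, so the votes show
    two opposing joints into the donor locus, bracketing the copied
    interval.  Pairing them, forward-building the implied insert-carrying
    fusion, and verifying the joint window against the reads recovers the
    host junction no single read spans.
    """
    from .model import AlleleArchitecture, EditEvent, apply_event, \
        render_sequence as _render
    by_donor: dict[str, list] = {}
    for j, n in voted:
        if j.orientation != "opposing" or n < 2:
            continue
        for (dl, dt), (pl, pt) in ((j.side5, j.side3), (j.side3, j.side5)):
            if dl == pl:
                continue
            by_donor.setdefault(dl, []).append((dt, pl, pt, n))
    out = []
    for donor, edges in sorted(by_donor.items()):
        for t_hi, p_hi, pt_hi, n1 in edges:
            for t_lo, p_lo, pt_lo, n2 in edges:
                if p_hi == p_lo or not 0 < t_hi - t_lo <= max_insert:
                    continue
                try:
                    g_hi, g_lo = array.gene(p_hi), array.gene(p_lo)
                    a_hi = g_hi.t_to_axis(pt_hi)
                    a_lo = g_lo.t_to_axis(pt_lo)
                except (KeyError, ValueError):
                    continue
                if g_hi.contig != g_lo.contig or a_hi == a_lo:
                    continue
                ev = EditEvent(
                    "templated_insert_fusion",
                    tuple(sorted((a_hi, a_lo))), g_hi.contig,
                    insert_source=(donor, t_lo, t_hi - t_lo))
                base = AlleleArchitecture.identity(array, g_hi.contig)
                try:
                    arch = apply_event(base, ev, array)
                except Exception:
                    continue
                juncs = junction_set(arch, array, provenance="read_pair")
                if len(juncs) != 1:
                    continue
                j = juncs[0]
                rendered = _render(arch, array)
                joint = min(ev.breakpoints)
                ins = t_hi - t_lo
                w_l = rendered[max(0, joint - 30):joint + min(20, ins)]
                w_r = rendered[joint + ins - min(20, ins):joint + ins + 30]
                def attested(w):
                    rw = revcomp(w)
                    return any(w in p.r1 or w in p.r2 or rw in p.r1
                               or rw in p.r2 for p in reads)
                if attested(w_l) and attested(w_r):
                    out.append((j, n1 + n2))
    return out


def _is_small_indel_joint(j: Junction, max_indel: int = 25) -> bool:
    """Same-locus joints with a tiny offset gap are inline indels at a cut
    site, not structural junctions."""
    if j.orientation != "productive" or j.side5[0] != j.side3[0]:
        return False
    return abs(j.side5[1] - j.side3[1]) <= max_indel and \
        abs(j.net_indel) <= max_indel


def collect_capture_evidence(reads: list[ReadPair], array: TandemArrayModel,
                             ref: Optional[ReferenceIndex] = None,
                             insert_mean: float = 550.0,
                             insert_sd: float = 60.0,
                             window: int = 200,
                             min_support: int = 3) -> CaptureEvidence:
    """Run the full capture analysis for one line."""
    ref = ref or ReferenceIndex(array.contigs)
    aligns = map_reads(reads, ref, insert_mean, insert_sd)
    profile = coverage_profile(aligns, array, window)
    ev = CaptureEvidence(
        alignments=aligns,
        profile=profile,
        gene_depth=gene_mean_depth(profile, array, window),
        dropouts=detect_dropouts(profile, array, window),
        clusters=detect_discordant(aligns, array, insert_mean, min_support),
    )
    low_voted, ev.indel_evidence = read_vote_junctions(
        reads, aligns, ref, array, min_votes=2)
    voted = [(j, n) for j, n in low_voted if n >= min_support]
    # a templated insert's host joint is visible only through its two edge
    # views; synthesize and verify it before anything else
    for j, n in synthesize_templated_junctions(low_voted, array, ref, reads):
        if j.signature() not in {x.signature() for x, _ in voted}:
            voted.append((j, n))
    # rank: (evidence tier, support) — direct read votes outrank assembled
    # contigs, which can be chimeric
    supported: list[tuple[Junction, tuple[int, int]]] = \
        [(j, (1, n)) for j, n in voted]
    ev.junctions = [j for j, _ in voted]
    seen = {j.signature() for j in ev.junctions}

    by_id = {p.read_id: p for p in reads}
    for cl in ev.clusters:
        covered = any({j.side5[0], j.side3[0]} <= set(cl.loci)
                      for j in ev.junctions)
        if covered:
            continue
        # assembly fallback for joints no single read resolves (e.g. a
        # templated insert leaves <50 bp of flank inside any one read):
        # cluster pairs plus reads mapped in the windows extending inward
        # from the two hulls, where junction-spanning reads land
        picked = list(cl.pair_ids[:24])
        win_l = (cl.left_contig, cl.left_span[1] - 100,
                 cl.left_span[1] + insert_mean + 100)
        win_r = (cl.right_contig, cl.right_span[0] - insert_mean - 100,
                 cl.right_span[0] + 100)
        for pa in aligns:
            if len(picked) >= 48:
                break
            for e in (pa.end1, pa.end2):
                if e is None:
                    continue
                for contig, lo, hi in (win_l, win_r):
                    if e.contig == contig and e.start < hi and e.end > lo:
                        picked.append(pa.pair_id)
                        break
        seqs = []
        for pid in dict.fromkeys(picked):
            p = by_id.get(pid)
            if p:
                seqs += [p.r1, p.r2]
        j = assemble_junction(
            seqs, ref, array,
            want_orientation=CLUSTER_ORIENTATION_PRIOR.get(cl.orientation),
            preferred_loci=cl.loci)
        if j is None:
            ev.unassembled.append(cl)
        elif _is_small_indel_joint(j):
            ev.indel_evidence.append(j)
        elif j.signature() not in seen:
            seen.add(j.signature())
            ev.junctions.append(j)
            supported.append((j, (0, cl.support)))

    # a read crossing only one edge of a templated insert reports a spurious
    # junction into the donor locus; once the full three-way joint is known,
    # suppress those edge views
    kept = []
    for j in ev.junctions:
        edge_view = False
        for o in ev.junctions:
            if o is j or not o.insert_source or len(o.inserted) < 25 \
                    or o.orientation != "productive":
                continue
            locus, t0, ilen = o.insert_source
            host_sides = {o.side5[0], o.side3[0]}
            for gid, t in (j.side5, j.side3):
                other = j.side3[0] if (gid, t) == j.side5 else j.side5[0]
                if gid == locus and t0 - 10 <= t <= t0 + ilen + 10 \
                        and other in host_sides:
                    edge_view = True
        if not edge_view:
            kept.append(j)
    ev.junctions = kept

    # one haplotype uses each gene portion (head = [0,t), tail = [t,L)) at
    # most once: junctions competing for the same portion are mutually
    # exclusive, and the better-supported one wins
    support = {j.signature(): n for j, n in supported}
    accepted: list[Junction] = []
    for j in sorted(ev.junctions,
                    key=lambda j: (tuple(-x for x in
                                         support.get(j.signature(), (0, 0))),
                                   j.signature())):
        if not any(_portion_conflict(j, a) for a in accepted):
            accepted.append(j)
    ev.junctions = accepted
    return ev
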