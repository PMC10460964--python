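"""Data model for tandemly arrayed genes, edit events, and allele architectures.

A tandem array lives on a left-to-right *axis* (a contig) in 0-based,
half-open coordinates.  Paralogous genes are placed on the ``-`` strand of
the axis by default, so that a deletion between Cas9 cuts in gene *i* and
gene *j* (i left of j on the axis) fuses the 5' portion of *j* to the 3'
portion of *i* and is named ``j-i`` — the convention used for fusion
alleles in tandem-array editing studies.

An :class:`AlleleArchitecture` is a segment-level haplotype: an ordered
list of oriented source intervals plus inline (small indel) edits.  Edit
events compose sequentially on the architecture; breakpoints are given in
source-axis coordinates and translated to the current rendered sequence
internally, so a breakpoint falling in an already-deleted region raises
:class:`StaleBreakpointError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

__all__ = [
    "revcomp",
    "GeneLocus",
    "GuideDesign",
    "TandemArrayModel",
    "EditEvent",
    "Segment",
    "InlineEdit",
    "AlleleArchitecture",
    "Junction",
    "StaleBreakpointError",
    "EditConflictError",
    "validate_guide",
    "apply_event",
    "render_sequence",
    "junction_set",
    "frame_status",
    "gene_states",
    "TruthCall",
]

_COMPLEMENT = str.maketrans("ACGTNRYSWKMacgtn", "TGCANYRSWMKtgcan")

# IUPAC nucleotide codes used for PAM patterns.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_match(pattern: str, seq: str) -> bool:
    if len(pattern) != len(seq):
        return False
    return all(b in IUPAC[p] for p, b in zip(pattern, seq))


class StaleBreakpointError(ValueError):
    """A breakpoint refers to sequence no longer present in the architecture."""


class EditConflictError(ValueError):
    """Two edits overlap in a way that has no consistent rendering."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneLocus:
    """A gene (or pseudogene) on the array axis.

    ``interval`` is [start, end) on the axis; ``strand`` is the gene's
    transcription strand relative to the axis; ``cds_blocks`` are axis
    intervals; ``cut_point`` is an axis *boundary* (between bases) for
    non-pseudogenes.
    """

    id: str
    interval: tuple[int, int]
    strand: str
    cds_blocks: tuple[tuple[int, int], ...] = ()
    cut_point: Optional[int] = None
    is_pseudogene: bool = False
    contig: str = "chr10"

    def __post_init__(self):
        s, e = self.interval
        if not s < e:
            raise ValueError(f"{self.id}: empty interval {self.interval}")
        if self.strand not in "+-":
            raise ValueError(f"{self.id}: strand must be + or -")
        prev = s
        for bs, be in self.cds_blocks:
            if not (s <= bs < be <= e):
                raise ValueError(f"{self.id}: CDS block {(bs, be)} outside gene")
            if bs < prev:
                raise ValueError(f"{self.id}: CDS blocks overlap or unsorted")
            prev = be
        if self.is_pseudogene:
            if self.cut_point is not None:
                raise ValueError(f"{self.id}: pseudogene cannot carry a cut point")
        else:
            if self.cut_point is None or not (s < self.cut_point < e):
                raise ValueError(f"{self.id}: cut point must lie inside the gene")

    @property
    def start(self) -> int:
        return self.interval[0]

    @property
    def end(self) -> int:
        return self.interval[1]

    @property
    def length(self) -> int:
        return self.end - self.start

    def axis_to_t(self, boundary: int) -> int:
        """Axis boundary -> transcription-coordinate boundary (0 at the 5' end)."""
        if self.strand == "+":
            return boundary - self.start
        return self.end - boundary

    def t_to_axis(self, t: int) -> int:
        if self.strand == "+":
            return self.start + t
        return self.end - t

    def in_cds(self, boundary: int) -> bool:
        """True if the axis boundary falls strictly inside a CDS block."""
        return any(bs < boundary < be for bs, be in self.cds_blocks)


@dataclass(frozen=True)
class GuideDesign:
    """A single-guide design: 20-nt spacer, IUPAC PAM, blunt cut offset.

    ``cut_offset`` counts base pairs from the PAM-proximal end of the
    spacer (3 for SpCas9).
    """

    spacer: str
    pam: str = "NGG"
    cut_offset: int = 3

    def __post_init__(self):
        if not set(self.spacer) <= set("ACGT"):
            raise ValueError("spacer must be plain ACGT")
        if not 1 <= self.cut_offset <= len(self.spacer) - 1:
            raise ValueError("cut_offset out of range")
        if not set(self.pam) <= set(IUPAC):
            raise ValueError("PAM must be IUPAC letters")


@dataclass
class TandemArrayModel:
    """The reference array: contig sequences, ordered loci, guide, variants."""

    contigs: dict[str, str]
    genes: list[GeneLocus]
    guide: GuideDesign
    diagnostic_variants: dict[str, list[tuple[int, str]]] = field(default_factory=dict)

    def __post_init__(self):
        by_contig: dict[str, list[GeneLocus]] = {}
        for g in self.genes:
            if g.contig not in self.contigs:
                raise ValueError(f"{g.id}: unknown contig {g.contig}")
            if g.end > len(self.contigs[g.contig]):
                raise ValueError(f"{g.id}: interval beyond contig end")
            by_contig.setdefault(g.contig, []).append(g)
        for contig, loci in by_contig.items():
            loci = sorted(loci, key=lambda g: g.start)
            for a, b in zip(loci, loci[1:]):
                if a.end > b.start:
                    raise ValueError(f"overlapping loci {a.id}/{b.id} on {contig}")

    # -- lookups ------------------------------------------------------------

    def gene(self, gene_id: str) -> GeneLocus:
        for g in self.genes:
            if g.id == gene_id:
                return g
        raise KeyError(gene_id)

    def array_genes(self) -> list[GeneLocus]:
        return [g for g in self.genes if not g.is_pseudogene]

    def pseudogenes(self) -> list[GeneLocus]:
        return [g for g in self.genes if g.is_pseudogene]

    def genes_on(self, contig: str) -> list[GeneLocus]:
        return sorted((g for g in self.genes if g.contig == contig),
                      key=lambda g: g.start)

    def locus_at(self, contig: str, boundary: int) -> tuple[GeneLocus, int]:
        """Nearest locus on ``contig`` and the boundary's t-offset in it."""
        loci = self.genes_on(contig)
        if not loci:
            raise KeyError(f"no loci on {contig}")
        best = min(loci, key=lambda g: max(g.start - boundary, boundary - g.end, 0))
        return best, best.axis_to_t(boundary)

    def gene_sequence(self, gene_id: str) -> str:
        """Locus sequence in transcription orientation."""
        g = self.gene(gene_id)
        seq = self.contigs[g.contig][g.start:g.end]
        return revcomp(seq) if g.strand == "-" else seq


# ---------------------------------------------------------------------------
# Guide validation
# ---------------------------------------------------------------------------

def _spacer_matches(seq: str, guide: GuideDesign) -> list[int]:
    """Start offsets of exact spacer+PAM matches in ``seq`` (one strand)."""
    hits = []
    n, m = len(guide.spacer), len(guide.pam)
    start = 0
    while True:
        i = seq.find(guide.spacer, start)
        if i < 0:
            break
        if i + n + m <= len(seq) and iupac_match(guide.pam, seq[i + n:i + n + m]):
            hits.append(i)
        start = i + 1
    return hits


@dataclass(frozen=True)
class GuideReport:
    locus_id: str
    is_pseudogene: bool
    n_matches: int
    match_t_offsets: tuple[int, ...]
    violation: bool


def validate_guide(array: TandemArrayModel,
                   guide: Optional[GuideDesign] = None) -> list[GuideReport]:
    """Per-locus guide-target report.

    Every non-pseudogene must contain exactly one spacer+PAM match (on
    either strand of the locus) and every pseudogene must contain none —
    the variant-free consensus design.  Violations are flagged, never
    silently dropped.
    """
    guide = guide or array.guide
    reports = []
    for g in array.genes:
        fwd = array.gene_sequence(g.id)
        hits = [(i, "+") for i in _spacer_matches(fwd, guide)]
        hits += [(i, "-") for i in _spacer_matches(revcomp(fwd), guide)]
        n = len(hits)
        violation = (n > 0) if g.is_pseudogene else (n != 1)
        reports.append(GuideReport(
            locus_id=g.id,
            is_pseudogene=g.is_pseudogene,
            n_matches=n,
            match_t_offsets=tuple(i for i, _ in hits),
            violation=violation,
        ))
    return reports


def guide_cut_t_offset(array: TandemArrayModel, gene_id: str) -> int:
    """Cut boundary in transcription coordinates of ``gene_id``."""
    g = array.gene(gene_id)
    if g.cut_point is None:
        raise ValueError(f"{gene_id} has no cut point")
    return g.axis_to_t(g.cut_point)


# ---------------------------------------------------------------------------
# Events and architectures
# ---------------------------------------------------------------------------

EVENT_KINDS = (
    "small_indel",
    "local_deletion",
    "dropout_fusion",
    "inversion",
    "translocation",
    "templated_insert_fusion",
)

MAX_SMALL_INDEL = 25
MAX_TEMPLATED_INSERT = 200


@dataclass(frozen=True)
class EditEvent:
    """One repair outcome applied to an architecture.

    Breakpoints are source-axis boundaries on ``contig``.  Two-breakpoint
    kinds (dropout/local deletion/inversion/templated insert) require
    pos_a < pos_b on one contig; translocation takes one breakpoint plus a
    ``partner`` (contig, boundary, orientation) on a different contig.
    """

    kind: str
    breakpoints: tuple[int, ...]
    contig: str = "chr10"
    indel_size: int = 0
    inserted_seq: str = ""
    insert_source: Optional[tuple[str, int, int]] = None  # (gene id, t offset, length)
    partner: Optional[tuple[str, int, str]] = None  # (contig, boundary, orientation)

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        two_bp = {"local_deletion", "dropout_fusion", "inversion",
                  "templated_insert_fusion"}
        if self.kind in two_bp:
            if len(self.breakpoints) != 2 or not self.breakpoints[0] < self.breakpoints[1]:
                raise ValueError(f"{self.kind} needs two ordered breakpoints")
        elif len(self.breakpoints) != 1:
            raise ValueError(f"{self.kind} takes one breakpoint")
        if self.kind == "small_indel":
            if self.indel_size == 0 or abs(self.indel_size) > MAX_SMALL_INDEL:
                raise ValueError("small_indel size out of range")
            if self.indel_size > 0 and len(self.inserted_seq) != self.indel_size:
                raise ValueError("insertion requires inserted_seq of matching length")
        if self.kind == "translocation":
            if self.partner is None:
                raise ValueError("translocation requires a partner")
            if self.partner[0] == self.contig:
                raise ValueError("translocation partner must be on a different contig")
        if self.kind == "templated_insert_fusion":
            if self.insert_source is None:
                raise ValueError("templated insert requires insert_source")
            if self.insert_source[2] > MAX_TEMPLATED_INSERT:
                raise ValueError("templated insert longer than cap")


@dataclass(frozen=True)
class Segment:
    contig: str
    start: int
    end: int
    orient: str  # '+' keeps axis orientation, '-' is reverse-complemented

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("empty segment")
        if self.orient not in "+-":
            raise ValueError("orient must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class InlineEdit:
    """A small indel pinned to a source boundary.

    ``indel_size`` < 0 deletes that many bases following the boundary in
    rendered orientation; > 0 inserts ``inserted_seq`` at the boundary.
    """

    contig: str
    pos: int  # source-axis boundary
    indel_size: int
    inserted_seq: str = ""
    insert_source: Optional[tuple[str, int, int]] = None

    def __post_init__(self):
        if self.indel_size == 0:
            raise ValueError("zero-size inline edit")
        if self.indel_size > 0 and len(self.inserted_seq) != self.indel_size:
            raise ValueError("inserted_seq length mismatch")


@dataclass
class AlleleArchitecture:
    """Ordered oriented source intervals plus inline edits."""

    segments: list[Segment]
    inline_edits: list[InlineEdit] = field(default_factory=list)

    @classmethod
    def identity(cls, array: TandemArrayModel, contig: str = "chr10") -> "AlleleArchitecture":
        return cls([Segment(contig, 0, len(array.contigs[contig]), "+")])

    # -- source <-> rendered coordinate plumbing ----------------------------

    def _edit_segment_index(self, edit: InlineEdit) -> Optional[int]:
        """Segment whose rendered direction contains the bases after the edit boundary."""
        for i, s in enumerate(self.segments):
            if s.contig != edit.contig:
                continue
            if s.orient == "+" and s.start <= edit.pos < s.end:
                return i
            if s.orient == "-" and s.start < edit.pos <= s.end:
                return i
        return None

    def _segment_edits(self, index: int) -> list[tuple[int, InlineEdit]]:
        """(rendered offset within segment, edit) pairs for segment ``index``."""
        seg = self.segments[index]
        out = []
        for e in self.inline_edits:
            if self._edit_segment_index(e) != index:
                continue
            off = (e.pos - seg.start) if seg.orient == "+" else (seg.end - e.pos)
            out.append((off, e))
        return sorted(out)

    def locate(self, contig: str, boundary: int) -> tuple[int, int]:
        """Map a source boundary to (segment index, rendered offset in segment).

        A boundary on a segment edge resolves to the segment whose interior
        follows it; raises StaleBreakpointError when the position was
        deleted from the architecture.
        """
        for i, s in enumerate(self.segments):
            if s.contig != contig:
                continue
            if s.start <= boundary <= s.end:
                off = (boundary - s.start) if s.orient == "+" else (s.end - boundary)
                return i, off
        raise StaleBreakpointError(f"boundary {contig}:{boundary} not in architecture")

    def rendered_position(self, contig: str, boundary: int) -> int:
        """Source boundary -> boundary on the rendered sequence (edits ignored)."""
        i, off = self.locate(contig, boundary)
        return sum(s.length for s in self.segments[:i]) + off

    def rendered_positions(self, contig: str, boundary: int) -> list[int]:
        """All rendered boundaries a source boundary maps to.

        A boundary sitting on a segment edge (e.g. an old inversion
        breakpoint) maps to both edges of the moved block.
        """
        out = []
        pos = 0
        for s in self.segments:
            if s.contig == contig and s.start <= boundary <= s.end:
                off = (boundary - s.start) if s.orient == "+" \
                    else (s.end - boundary)
                out.append(pos + off)
            pos += s.length
        if not out:
            raise StaleBreakpointError(
                f"boundary {contig}:{boundary} not in architecture")
        return sorted(set(out))

    def split_at_rendered(self, rpos: int) -> int:
        """Ensure a segment boundary at rendered position ``rpos``; return
        the index of the segment that starts there."""
        pos = 0
        for i, s in enumerate(self.segments):
            if pos <= rpos <= pos + s.length:
                off = rpos - pos
                if off == 0:
                    return i
                if off == s.length:
                    return i + 1
                if s.orient == "+":
                    parts = [Segment(s.contig, s.start, s.start + off, "+"),
                             Segment(s.contig, s.start + off, s.end, "+")]
                else:
                    parts = [Segment(s.contig, s.end - off, s.end, "-"),
                             Segment(s.contig, s.start, s.end - off, "-")]
                self.segments[i:i + 1] = parts
                return i + 1
            pos += s.length
        raise StaleBreakpointError(f"rendered position {rpos} out of range")

    def split_at(self, contig: str, boundary: int) -> int:
        """Ensure a segment boundary at the source boundary; return the index
        of the segment that *starts* there."""
        i, off = self.locate(contig, boundary)
        s = self.segments[i]
        if off == 0:
            return i
        if off == s.length:
            return i + 1
        if s.orient == "+":
            left = Segment(s.contig, s.start, boundary, "+")
            right = Segment(s.contig, boundary, s.end, "+")
        else:
            left = Segment(s.contig, boundary, s.end, "-")
            right = Segment(s.contig, s.start, boundary, "-")
        self.segments[i:i + 1] = [left, right]
        return i + 1

    def source_intervals(self, r_start: int, r_end: int) -> list[Segment]:
        """Source segments underlying the rendered interval [r_start, r_end).

        Inline-edit length changes are ignored (segment-resolution mapping);
        adequate for locus composition queries.
        """
        out = []
        pos = 0
        for s in self.segments:
            lo, hi = max(pos, r_start), min(pos + s.length, r_end)
            if lo < hi:
                if s.orient == "+":
                    out.append(Segment(s.contig, s.start + (lo - pos),
                                       s.start + (hi - pos), "+"))
                else:
                    out.append(Segment(s.contig, s.end - (hi - pos),
                                       s.end - (lo - pos), "-"))
            pos += s.length
        return out


# ---------------------------------------------------------------------------
# Forward model operations
# ---------------------------------------------------------------------------

def _copy(arch: AlleleArchitecture) -> AlleleArchitecture:
    return AlleleArchitecture(list(arch.segments), list(arch.inline_edits))


def _fetch_insert(array: TandemArrayModel, source: tuple[str, int, int]) -> str:
    gene_id, t_off, length = source
    g = array.gene(gene_id)
    seq = array.gene_sequence(gene_id)
    if not 0 <= t_off <= t_off + length <= g.length:
        raise ValueError(f"insert source outside {gene_id}")
    return seq[t_off:t_off + length]


def apply_event(arch: AlleleArchitecture, event: EditEvent,
                array: TandemArrayModel) -> AlleleArchitecture:
    """Apply one edit event; returns a new architecture.

    Events compose sequentially: breakpoints are source-axis boundaries and
    must still be present in the architecture (else StaleBreakpointError).
    """
    new = _copy(arch)
    kind = event.kind

    if kind == "small_indel":
        (pos,) = event.breakpoints
        edit = InlineEdit(event.contig, pos, event.indel_size, event.inserted_seq)
        idx = new._edit_segment_index(edit)
        if idx is None:
            raise StaleBreakpointError(f"indel boundary {event.contig}:{pos} deleted")
        seg = new.segments[idx]
        my_off = (pos - seg.start) if seg.orient == "+" else (seg.end - pos)
        for off, other in new._segment_edits(idx):
            lo = min(off, my_off)
            hi = max(off, my_off)
            lo_span = -other.indel_size if (lo == off and other.indel_size < 0) else \
                (-event.indel_size if (lo == my_off and event.indel_size < 0) else 0)
            if off == my_off or lo + lo_span > hi:
                raise EditConflictError(
                    f"inline edits collide at {event.contig}:{pos}")
        if event.indel_size < 0 and my_off - event.indel_size > seg.length:
            raise EditConflictError("deletion runs past segment end")
        new.inline_edits.append(edit)
        return new

    if kind in ("dropout_fusion", "local_deletion", "templated_insert_fusion"):
        pos_a, pos_b = event.breakpoints
        # breakpoints are unordered cut *sites*; a site on an old segment
        # edge maps to both edges of the moved block — take the widest span
        cand = new.rendered_positions(event.contig, pos_a) \
            + new.rendered_positions(event.contig, pos_b)
        ra, rb = min(cand), max(cand)
        if ra == rb:
            raise EditConflictError("deletion breakpoints coincide")
        ia = new.split_at_rendered(ra)
        ib = new.split_at_rendered(rb)
        new.segments[ia:ib] = []
        # drop inline edits that lived on removed sequence
        new.inline_edits = [e for e in new.inline_edits
                            if new._edit_segment_index(e) is not None]
        inserted = event.inserted_seq
        src = event.insert_source
        if kind == "templated_insert_fusion" and src is not None and not inserted:
            inserted = _fetch_insert(array, src)
        if inserted:
            if ia >= len(new.segments):
                raise EditConflictError("junction insert at molecule end")
            follow = new.segments[ia]
            bpos = follow.start if follow.orient == "+" else follow.end
            new.inline_edits.append(InlineEdit(follow.contig, bpos,
                                               len(inserted), inserted, src))
        return new

    if kind == "inversion":
        pos_a, pos_b = event.breakpoints
        cand = new.rendered_positions(event.contig, pos_a) \
            + new.rendered_positions(event.contig, pos_b)
        ra, rb = min(cand), max(cand)
        if ra == rb:
            raise EditConflictError("inversion breakpoints coincide")
        ia = new.split_at_rendered(ra)
        ib = new.split_at_rendered(rb)
        flipped = [Segment(s.contig, s.start, s.end, "-" if s.orient == "+" else "+")
                   for s in reversed(new.segments[ia:ib])]
        new.segments[ia:ib] = flipped
        return new

    if kind == "translocation":
        (pos,) = event.breakpoints
        idx = new.split_at(event.contig, pos)
        contig, p, orient = event.partner
        if contig not in array.contigs:
            raise ValueError(f"unknown partner contig {contig}")
        clen = len(array.contigs[contig])
        if orient == "+":
            tail = Segment(contig, p, clen, "+")
        else:
            tail = Segment(contig, 0, p, "-")
        new.segments[idx:] = [tail]
        new.inline_edits = [e for e in new.inline_edits
                            if new._edit_segment_index(e) is not None]
        return new

    raise AssertionError(kind)


def render_sequence(arch: AlleleArchitecture, array: TandemArrayModel) -> str:
    """Deterministic rendering of an architecture into a DNA string."""
    parts = []
    for i, seg in enumerate(arch.segments):
        chunk = array.contigs[seg.contig][seg.start:seg.end]
        if seg.orient == "-":
            chunk = revcomp(chunk)
        for off, e in sorted(arch._segment_edits(i), reverse=True):
            if e.indel_size > 0:
                chunk = chunk[:off] + e.inserted_seq + chunk[off:]
            else:
                d = -e.indel_size
                if off + d > len(chunk):
                    raise EditConflictError("deletion runs past segment end")
                chunk = chunk[:off] + chunk[off + d:]
        parts.append(chunk)
    return "".join(parts)


# ---------------------------------------------------------------------------
# Junctions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Junction:
    """An observed or simulated joint between two loci.

    ``side5``/``side3`` are (locus id, t-offset boundary) in each locus's
    transcription coordinates.  For opposing joints the 5'/3' roles are not
    defined; sides are then reported in rendered order with orientation
    ``"opposing"``.
    """

    side5: tuple[str, int]
    side3: tuple[str, int]
    orientation: str  # "productive" | "opposing"
    inserted: str = ""
    insert_source: Optional[tuple[str, int, int]] = None
    net_indel: int = 0
    provenance: str = "truth"
    # which transcript portion of each side the joint consumes:
    # ("head", t) = [0, t), ("tail", t) = [t, gene length)
    portions: tuple[tuple[str, str, int], ...] = ()

    def signature(self) -> tuple:
        """Canonical comparison key: orientation + locus pair.

        Offsets, inserted bases, and the templated-insert source are kept
        out of the key: assembly assigns microhomologous joints and
        near-identical insert donors ambiguously, and evidence from
        different layers must still collapse onto one junction.
        """
        if self.orientation == "productive":
            return ("P", self.side5[0], self.side3[0])
        pair = tuple(sorted((self.side5[0], self.side3[0])))
        return ("O", pair[0], pair[1])


def _boundary_insert(arch: AlleleArchitecture, seg_index: int) -> Optional[InlineEdit]:
    """Insertion inline edit sitting exactly at the start of segment ``seg_index``."""
    seg = arch.segments[seg_index]
    bpos = seg.start if seg.orient == "+" else seg.end
    for e in arch.inline_edits:
        if (e.indel_size > 0 and e.contig == seg.contig and e.pos == bpos
                and arch._edit_segment_index(e) == seg_index):
            return e
    return None


def _boundary_deletion(arch: AlleleArchitecture, seg_index: int) -> int:
    """Total deleted bases from inline deletions at the start of segment ``seg_index``."""
    seg = arch.segments[seg_index]
    bpos = seg.start if seg.orient == "+" else seg.end
    total = 0
    for e in arch.inline_edits:
        if (e.indel_size < 0 and e.contig == seg.contig and e.pos == bpos
                and arch._edit_segment_index(e) == seg_index):
            total += -e.indel_size
    return total


def _boundary_deletion_left(arch: AlleleArchitecture, seg_index: int) -> int:
    """Deleted bases from inline deletions reaching the rendered end of
    segment ``seg_index`` (the other flank of the following junction)."""
    seg = arch.segments[seg_index]
    total = 0
    for e in arch.inline_edits:
        if e.indel_size >= 0 or e.contig != seg.contig:
            continue
        if arch._edit_segment_index(e) != seg_index:
            continue
        d = -e.indel_size
        reaches_end = (e.pos + d == seg.end) if seg.orient == "+" \
            else (e.pos - d == seg.start)
        if reaches_end:
            total += d
    return total


def _reference_adjacent(a: Segment, b: Segment) -> bool:
    if a.contig != b.contig or a.orient != b.orient:
        return False
    return (a.end == b.start) if a.orient == "+" else (b.end == a.start)


def junction_set(arch: AlleleArchitecture, array: TandemArrayModel,
                 provenance: str = "truth") -> list[Junction]:
    """One Junction per adjacent segment pair that is not reference-adjacent."""
    out = []
    for i in range(len(arch.segments) - 1):
        a, b = arch.segments[i], arch.segments[i + 1]
        if _reference_adjacent(a, b):
            continue
        ba = a.end if a.orient == "+" else a.start  # source boundary at a's rendered end
        bb = b.start if b.orient == "+" else b.end
        locus_a, ta = array.locus_at(a.contig, ba)
        locus_b, tb = array.locus_at(b.contig, bb)
        ea = locus_a.strand if a.orient == "+" else ("-" if locus_a.strand == "+" else "+")
        eb = locus_b.strand if b.orient == "+" else ("-" if locus_b.strand == "+" else "+")
        ins_edit = _boundary_insert(arch, i + 1)
        inserted = ins_edit.inserted_seq if ins_edit else ""
        insert_source = ins_edit.insert_source if ins_edit else None
        del_adj = _boundary_deletion(arch, i + 1) + \
            _boundary_deletion_left(arch, i)
        port_a = (locus_a.id, "head" if ea == "+" else "tail", ta)
        port_b = (locus_b.id, "tail" if eb == "+" else "head", tb)
        if ea == eb:
            if ea == "+":
                s5, s3 = (locus_a.id, ta), (locus_b.id, tb)
            else:
                s5, s3 = (locus_b.id, tb), (locus_a.id, ta)
            net = (s5[1] - s3[1]) + len(inserted) - del_adj
            out.append(Junction(s5, s3, "productive", inserted, insert_source,
                                net, provenance, (port_a, port_b)))
        else:
            out.append(Junction((locus_a.id, ta), (locus_b.id, tb), "opposing",
                                inserted, insert_source, 0, provenance,
                                (port_a, port_b)))
    return out


# ---------------------------------------------------------------------------
# Reading-frame arithmetic
# ---------------------------------------------------------------------------

def frame_status(obj, array: TandemArrayModel) -> str:
    """Classify a Junction or an (gene id, axis boundary, indel size) indel.

    ``in_frame`` iff the joint/indel lies in coding sequence (both sides,
    for a junction) and the net coding-length change is 0 mod 3;
    ``noncoding`` when outside CDS; otherwise ``frameshift``.
    """
    if isinstance(obj, Junction):
        if obj.orientation == "opposing":
            return "frameshift"
        g5 = array.gene(obj.side5[0])
        g3 = array.gene(obj.side3[0])
        p5 = g5.t_to_axis(obj.side5[1])
        p3 = g3.t_to_axis(obj.side3[1])
        if not (g5.in_cds(p5) and g3.in_cds(p3)):
            return "noncoding"
        return "in_frame" if obj.net_indel % 3 == 0 else "frameshift"
    gene_id, boundary, size = obj
    g = array.gene(gene_id)
    if not g.in_cds(boundary):
        return "noncoding"
    return "in_frame" if size % 3 == 0 else "frameshift"


# ---------------------------------------------------------------------------
# Per-gene truth derivation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruthCall:
    """Structural state of one gene in an architecture."""

    gene_id: str
    state: str  # native | indel | absent | fusion_5 | fusion_3 | inverted | rearranged | translocated
    indel: int = 0
    partner: Optional[str] = None
    junction_t: Optional[int] = None  # joint t-offset in this gene, if any


def gene_states(arch: AlleleArchitecture, array: TandemArrayModel,
                contig: str = "chr10") -> dict[str, TruthCall]:
    """Derive per-gene truth calls from segments, edits, and junctions."""
    juncs = junction_set(arch, array)
    by_gene: dict[str, list[Junction]] = {}
    for j in juncs:
        for side, (gid, t) in (("5", j.side5), ("3", j.side3)):
            if 0 <= t <= array.gene(gid).length:
                by_gene.setdefault(gid, []).append(j)

    out: dict[str, TruthCall] = {}
    for g in array.genes_on(contig):
        if g.is_pseudogene:
            continue
        pieces = []  # (covered bp, orient) per segment overlapping the gene
        for s in arch.segments:
            if s.contig != g.contig:
                continue
            lo, hi = max(s.start, g.start), min(s.end, g.end)
            if lo < hi:
                pieces.append((hi - lo, s.orient))
        covered = sum(p for p, _ in pieces)
        edits = [e for e in arch.inline_edits
                 if e.contig == g.contig and g.start <= e.pos <= g.end
                 and arch._edit_segment_index(e) is not None]
        gj = by_gene.get(g.id, [])

        if covered == 0:
            out[g.id] = TruthCall(g.id, "absent")
            continue

        # junction attached inside this gene?
        internal = [j for j in gj
                    if any(0 < t < g.length
                           for gid, t in (j.side5, j.side3) if gid == g.id)]
        if internal:
            j = internal[0]
            if j.orientation == "opposing":
                other = j.side3[0] if j.side5[0] == g.id else j.side5[0]
                t = j.side5[1] if j.side5[0] == g.id else j.side3[1]
                out[g.id] = TruthCall(g.id, "rearranged", partner=other, junction_t=t)
                continue
            if j.side5[0] == g.id and j.side3[0] == g.id:
                out[g.id] = TruthCall(g.id, "indel", indel=-(g.length - covered),
                                      junction_t=j.side5[1])
                continue
            role = "fusion_5" if j.side5[0] == g.id else "fusion_3"
            other = j.side3[0] if role == "fusion_5" else j.side5[0]
            t = j.side5[1] if role == "fusion_5" else j.side3[1]
            state = role
            if array.gene(other).contig != g.contig or array.gene(other).is_pseudogene:
                state = "translocated"
            out[g.id] = TruthCall(g.id, state, indel=j.net_indel,
                                  partner=other, junction_t=t)
            continue

        if covered == g.length and len(pieces) == 1:
            orient = pieces[0][1]
            indel = sum(e.indel_size for e in edits
                        if g.start < e.pos < g.end)
            if indel:
                out[g.id] = TruthCall(g.id, "indel", indel=indel)
            elif orient == "-":
                out[g.id] = TruthCall(g.id, "inverted")
            else:
                out[g.id] = TruthCall(g.id, "native")
            continue

        # partial coverage without an attached junction (e.g. molecule end)
        out[g.id] = TruthCall(g.id, "absent" if covered < g.length // 4 else "rearranged")
    return out
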