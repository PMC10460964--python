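"""Synthetic tandem-array editing: arrays, mutant populations, and reads.

The generator emulates the structure of a hemizygous ~100 kb array of
seven near-identical paralogs sharing one guide target in their second
exon, plus pseudogene loci on a sibling contig and a homoeologous contig.
Each simulated line receives 1-4 edit events (small indels, local
deletions, dropout fusions, inversions, translocations, templated-insert
fusions) applied through the forward model in :mod:`tagedit.model`, and a
ground-truth record is derived from the resulting architecture.

Reads are error-free by default: the inference pipeline targets structural
signal, not sequencing noise.  An optional uniform substitution rate is
available for robustness experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import (
    AlleleArchitecture,
    EditEvent,
    GeneLocus,
    GuideDesign,
    Junction,
    TandemArrayModel,
    TruthCall,
    apply_event,
    gene_states,
    junction_set,
    render_sequence,
    revcomp,
)

__all__ = [
    "SimulationConfig",
    "AmpliconLayout",
    "TruthRecord",
    "LineRecord",
    "build_array",
    "amplicon_primer_pair",
    "long_primer_pair",
    "simulate_population",
    "line_genome",
    "simulate_amplicon_reads",
    "simulate_capture_reads",
    "capture_identity",
]

BASES = "ACGT"

# Transcription-coordinate layout of the ancestral paralog (all offsets in bp).
GENE_LEN = 2400
EXONS_T = ((0, 300), (700, 1150), (1500, 1900), (2100, 2400))
SPACER_T = (900, 920)
PAM_T = (920, 923)
CUT_T = 917  # blunt cut 3 bp PAM-proximal
AMP_FWD_T = (840, 862)
AMP_REV_T = (1018, 1040)
LONG_FWD_T = (100, 122)
LONG_REV_T = (2050, 2072)
DIAG_T = (870, 885, 950, 990)  # two sites each side of the cut

MAIN_CONTIG = "chr10"
SHORT_CONTIG = "chr10_short"
HOM_CONTIG = "chr8"

GENE_MARGIN = 3000
GENE_SPACING = 16000  # start-to-start; span of 7 genes ~98 kb


@dataclass(frozen=True)
class AmpliconLayout:
    """Where the short amplicon sits in gene transcription coordinates."""

    fwd: tuple[int, int] = AMP_FWD_T
    rev: tuple[int, int] = AMP_REV_T
    cut: int = CUT_T

    @property
    def start(self) -> int:
        return self.fwd[0]

    @property
    def end(self) -> int:
        return self.rev[1]

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def cut_offset(self) -> int:
        return self.cut - self.start


@dataclass
class SimulationConfig:
    n_genes: int = 7
    gene_length: int = GENE_LEN
    gene_spacing: int = GENE_SPACING
    divergence: float = 0.01          # substitutions/bp between paralogs
    pseudo_divergence: float = 0.08
    control_divergence: float = 0.06
    n_lines: int = 50
    event_mix: dict = field(default_factory=lambda: {
        "small_indel": 0.50,
        "dropout_fusion": 0.20,
        "local_deletion": 0.10,
        "inversion": 0.10,
        "translocation": 0.05,
        "templated_insert_fusion": 0.05,
    })
    # indel spectrum: -1 and +1 dominate, remaining mass geometric on 2..25
    p_minus1: float = 0.30
    p_plus1: float = 0.30
    geometric_p: float = 0.35
    max_indel: int = 25
    p_joint_indel: float = 0.5        # chance a fusion joint carries a small indel
    templated_insert_len: int = 80
    hemizygous: bool = True
    read_len: int = 150
    insert_mean: float = 550.0
    insert_sd: float = 60.0
    capture_identity_threshold: float = 0.85
    capture_background: float = 0.01
    error_rate: float = 0.0

    def __post_init__(self):
        if self.n_genes < 2:
            raise ValueError("need at least two paralogs")
        total = sum(self.event_mix.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError("event mix weights must sum to 1")
        if not (0 <= self.p_minus1 and 0 <= self.p_plus1
                and self.p_minus1 + self.p_plus1 <= 1):
            raise ValueError("indel probabilities out of range")


# ---------------------------------------------------------------------------
# Array construction
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))

def _protected_positions(extra: tuple = ()) -> set[int]:
    prot: set[int] = set()
    for a, b in (SPACER_T, PAM_T, AMP_FWD_T, AMP_REV_T, LONG_FWD_T, LONG_REV_T):
        prot.update(range(a, b))
    prot.update(DIAG_T)
    prot.update(extra)
    return prot


def _diverge(seq: str, rate: float, rng: np.random.Generator,
             protected: set[int]) -> str:
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        if int(i) in protected:
            continue
        choices = [b for b in BASES if b != out[i]]
        out[i] = choices[rng.integers(3)]
    return "".join(out)


def _plant(seq: str, pos: int, base: str) -> str:
    return seq[:pos] + base + seq[pos + 1:]


def _diag_code(index: int) -> tuple[str, str, str, str]:
    """Distinct 4-base diagnostic code for paralog ``index`` (supports 16)."""
    a = BASES[index % 4]
    b = BASES[(index // 4) % 4]
    return (a, b, a, b)


def _disrupt(seq: str, window: tuple[int, int], rng: np.random.Generator,
             n: int = 2) -> str:
    """Plant ``n`` substitutions inside a window (kills exact primer/spacer sites)."""
    a, b = window
    if b > len(seq):
        return seq
    positions = np.linspace(a + 2, b - 3, n).astype(int)
    for p in positions:
        cur = seq[p]
        seq = _plant(seq, int(p), BASES[(BASES.index(cur) + 1) % 4])
    return seq


def amplicon_primer_pair(array: TandemArrayModel, pair_id: str = "amp") -> "PrimerPair":
    """Consensus short-amplicon primer pair (conserved across paralogs and
    the homoeologous control pseudogene)."""
    from .pcr import PrimerPair
    seq = array.gene_sequence("g1")
    return PrimerPair(pair_id, seq[AMP_FWD_T[0]:AMP_FWD_T[1]],
                      revcomp(seq[AMP_REV_T[0]:AMP_REV_T[1]]),
                      intended_targets=tuple(g.id for g in array.array_genes()))


def long_primer_pair(array: TandemArrayModel, pair_id: str = "multigene") -> "PrimerPair":
    """Consensus multigene (long) PCR pair spanning most of the gene body."""
    from .pcr import PrimerPair
    seq = array.gene_sequence("g1")
    return PrimerPair(pair_id, seq[LONG_FWD_T[0]:LONG_FWD_T[1]],
                      revcomp(seq[LONG_REV_T[0]:LONG_REV_T[1]]),
                      intended_targets=tuple(g.id for g in array.array_genes()))


def build_array(config: SimulationConfig, seed: int) -> TandemArrayModel:
    """Build a reference tandem array with paralogs, pseudogenes, and guide.

    Paralogs derive from one ancestral sequence by seeded substitution;
    each carries a unique diagnostic base code inside the amplicon window
    (one pair of sites on each side of the cut) unless divergence is zero.
    Pseudogenes carry spacer-disrupting changes and truncations.
    """
    rng = np.random.default_rng(seed)
    L = config.gene_length
    if L != GENE_LEN:
        raise ValueError("gene_length is fixed by the ancestral layout")

    ancestor = _random_seq(rng, L)
    # canonical PAM: make positions 921-922 "GG" so the spacer+NGG is real
    ancestor = _plant(_plant(ancestor, PAM_T[0] + 1, "G"), PAM_T[0] + 2, "G")
    spacer = ancestor[SPACER_T[0]:SPACER_T[1]]
    guide = GuideDesign(spacer=spacer, pam="NGG", cut_offset=3)

    protected = _protected_positions()
    gene_seqs = []
    for i in range(config.n_genes):
        s = _diverge(ancestor, config.divergence, rng, protected)
        if config.divergence > 0:
            code = _diag_code(i)
            for pos, base in zip(DIAG_T, code):
                s = _plant(s, pos, base)
        gene_seqs.append(s)

    # pseudogenes (all spacer-disrupted): one 5'-truncated copy downstream on
    # the main contig, two remnants on the sibling contig, one full-length
    # control on the homoeologous contig with intact amplicon primer sites.
    def pseudo_seq(rate, spacer_ok=False, keep_amp=False, keep_long=False,
                   t_range=None, internal_del=None, code_index=None):
        prot = set()
        if keep_amp:
            prot |= set(range(*AMP_FWD_T)) | set(range(*AMP_REV_T)) | set(DIAG_T)
        if keep_long:
            prot |= set(range(*LONG_FWD_T)) | set(range(*LONG_REV_T))
        s = _diverge(ancestor, rate, rng, prot)
        if code_index is not None and config.divergence > 0:
            for pos, base in zip(DIAG_T, _diag_code(code_index)):
                s = _plant(s, pos, base)
        if not spacer_ok:
            s = _disrupt(s, SPACER_T, rng)
        if not keep_amp:
            s = _disrupt(s, AMP_FWD_T, rng)
            s = _disrupt(s, AMP_REV_T, rng)
        if not keep_long:
            s = _disrupt(s, LONG_FWD_T, rng)
            s = _disrupt(s, LONG_REV_T, rng)
        if internal_del is not None:
            a, b = internal_del
            s = s[:a] + s[b:]
        elif t_range is not None:
            s = s[t_range[0]:t_range[1]]
        return s

    p_c10_1 = pseudo_seq(config.pseudo_divergence, t_range=(600, L))
    p_c10_2 = pseudo_seq(config.pseudo_divergence, keep_long=True,
                         internal_del=(600, 1600))
    p_c10_3 = pseudo_seq(config.pseudo_divergence, t_range=(700, L))
    p_c8 = pseudo_seq(config.control_divergence, keep_amp=True,
                      code_index=config.n_genes)

    # -- assemble contigs (genes on the minus strand of the axis) -----------
    genes: list[GeneLocus] = []
    diag: dict[str, list[tuple[int, str]]] = {}

    def place(contig_parts, contig_name, gene_id, tseq, at, is_pseudo,
              record_diag=False):
        contig_parts.append((at, revcomp(tseq)))
        start, end = at, at + len(tseq)
        if is_pseudo:
            locus = GeneLocus(gene_id, (start, end), "-", (), None, True, contig_name)
        else:
            cds = tuple(sorted((end - b, end - a) for a, b in EXONS_T))
            cut = end - CUT_T
            locus = GeneLocus(gene_id, (start, end), "-", cds, cut, False, contig_name)
            if record_diag:
                diag[gene_id] = [(end - 1 - t, revcomp(tseq[t]))
                                 for t in DIAG_T]
        genes.append(locus)
        return end

    def build_contig(length, placements):
        seq = list(_random_seq(rng, length))
        for at, block in placements:
            seq[at:at + len(block)] = block
        return "".join(seq)

    main_parts: list[tuple[int, str]] = []
    for i, s in enumerate(gene_seqs):
        at = GENE_MARGIN + i * config.gene_spacing
        place(main_parts, MAIN_CONTIG, f"g{i + 1}", s, at, False, record_diag=True)
    p1_at = GENE_MARGIN + (config.n_genes - 1) * config.gene_spacing + L + 2200
    place(main_parts, MAIN_CONTIG, "c10.1p", p_c10_1, p1_at, True)
    main_len = p1_at + len(p_c10_1) + GENE_MARGIN

    short_parts: list[tuple[int, str]] = []
    place(short_parts, SHORT_CONTIG, "c10.2p", p_c10_2, 3000, True)
    place(short_parts, SHORT_CONTIG, "c10.3p", p_c10_3, 10000, True)
    short_len = 10000 + len(p_c10_3) + 3000

    hom_parts: list[tuple[int, str]] = []
    place(hom_parts, HOM_CONTIG, "c8.1p", p_c8, 4000, True)
    hom_len = 4000 + len(p_c8) + 3000

    contigs = {
        MAIN_CONTIG: build_contig(main_len, main_parts),
        SHORT_CONTIG: build_contig(short_len, short_parts),
        HOM_CONTIG: build_contig(hom_len, hom_parts),
    }
    return TandemArrayModel(contigs=contigs, genes=genes, guide=guide,
                            diagnostic_variants=diag)


# ---------------------------------------------------------------------------
# Population simulation
# ---------------------------------------------------------------------------

@dataclass
class TruthRecord:
    line_id: str
    calls: dict[str, TruthCall]
    events: list[EditEvent]
    junctions: list[Junction]
    expected_amplicon: dict[str, tuple]


@dataclass
class LineRecord:
    line_id: str
    architecture: AlleleArchitecture
    truth: TruthRecord


def _draw_indel(rng: np.random.Generator, cfg: SimulationConfig) -> tuple[int, str]:
    u = rng.random()
    if u < cfg.p_minus1:
        return -1, ""
    if u < cfg.p_minus1 + cfg.p_plus1:
        return 1, BASES[rng.integers(4)]
    size = 2 + int(rng.geometric(cfg.geometric_p)) - 1
    size = min(size, cfg.max_indel)
    if rng.random() < 0.6:
        return -size, ""
    return size, _random_seq(rng, size)


def _sample_events(array: TandemArrayModel, cfg: SimulationConfig,
                   rng: np.random.Generator) -> list[EditEvent]:
    genes = array.array_genes()
    order = {g.id: i for i, g in enumerate(genes)}
    intact = set(order)
    kinds = sorted(cfg.event_mix)
    weights = np.array([cfg.event_mix[k] for k in kinds])
    weights = weights / weights.sum()
    n_events = int(rng.integers(1, 5))
    events: list[EditEvent] = []

    c10_3 = array.gene("c10.3p")
    partner_boundary = c10_3.end - (CUT_T - 700)  # homologous cut in the remnant

    for _ in range(n_events):
        if not intact:
            break
        kind = str(rng.choice(kinds, p=weights))
        pool = sorted(intact, key=order.get)
        if kind in ("dropout_fusion", "inversion", "templated_insert_fusion") \
                and len(pool) < 2:
            kind = "small_indel"
        if kind == "small_indel":
            gid = pool[int(rng.integers(len(pool)))]
            size, ins = _draw_indel(rng, cfg)
            events.append(EditEvent("small_indel", (array.gene(gid).cut_point,),
                                    MAIN_CONTIG, size, ins))
            intact.discard(gid)
        elif kind == "local_deletion":
            gid = pool[int(rng.integers(len(pool)))]
            cut = array.gene(gid).cut_point
            d = int(rng.integers(300, 2001))
            # transcription-downstream of the cut = axis-leftward (minus strand)
            events.append(EditEvent("local_deletion", (cut - d, cut), MAIN_CONTIG))
            intact.discard(gid)
        elif kind in ("dropout_fusion", "templated_insert_fusion"):
            i, j = sorted(rng.choice(len(pool), size=2, replace=False))
            ga, gb = pool[int(i)], pool[int(j)]
            pos_a = array.gene(ga).cut_point
            pos_b = array.gene(gb).cut_point
            if kind == "templated_insert_fusion":
                donors = [g.id for g in genes if g.id not in (ga, gb)]
                donor = donors[int(rng.integers(len(donors)))] if donors else ga
                src = (donor, CUT_T - cfg.templated_insert_len,
                       cfg.templated_insert_len)
                events.append(EditEvent("templated_insert_fusion", (pos_a, pos_b),
                                        MAIN_CONTIG, insert_source=src))
            else:
                events.append(EditEvent("dropout_fusion", (pos_a, pos_b),
                                        MAIN_CONTIG))
                if rng.random() < cfg.p_joint_indel:
                    size, ins = _draw_indel(rng, cfg)
                    events.append(EditEvent("small_indel", (pos_b,),
                                            MAIN_CONTIG, size, ins))
            for gid in pool:
                if order[ga] <= order[gid] <= order[gb]:
                    intact.discard(gid)
        elif kind == "inversion":
            i, j = sorted(rng.choice(len(pool), size=2, replace=False))
            ga, gb = pool[int(i)], pool[int(j)]
            events.append(EditEvent(
                "inversion",
                (array.gene(ga).cut_point, array.gene(gb).cut_point),
                MAIN_CONTIG))
            for gid in pool:
                if order[ga] <= order[gid] <= order[gb]:
                    intact.discard(gid)
        elif kind == "translocation":
            gid = pool[int(rng.integers(len(pool)))]
            events.append(EditEvent(
                "translocation", (array.gene(gid).cut_point,), MAIN_CONTIG,
                partner=(SHORT_CONTIG, partner_boundary, "+")))
            for g2 in pool:
                if order[g2] >= order[gid]:
                    intact.discard(g2)
    return events


def expected_amplicon_call(call: TruthCall, array: TandemArrayModel,
                           layout: AmpliconLayout = AmpliconLayout()) -> tuple:
    """Project a structural truth call onto the amplicon-visible category.

    Categories: ("native",), ("indel", n), ("fusion", "gJ-gI", net), ("na",).
    The projection encodes amplicon blind spots: joints upstream of the
    forward primer leave the 3' partner looking native and hide the 5'
    partner entirely.
    """
    st = call.state
    if st == "native" or st == "inverted":
        return ("native",)
    if st == "absent" or st == "rearranged" or st == "translocated":
        return ("na",)
    if st == "indel":
        if call.junction_t is None:
            return ("indel", call.indel)
        # local deletion starting at the cut: survives only if the reverse
        # primer site is retained
        del_end = call.junction_t - call.indel
        if call.junction_t >= layout.fwd[1] and del_end <= layout.rev[0]:
            return ("indel", call.indel)
        return ("na",)
    if st in ("fusion_5", "fusion_3"):
        t = call.junction_t
        if t == layout.cut:
            pair = (f"{call.gene_id}-{call.partner}" if st == "fusion_5"
                    else f"{call.partner}-{call.gene_id}")
            return ("fusion", pair, call.indel)
        if st == "fusion_3" and t is not None and t <= layout.fwd[1]:
            return ("native",)  # amplicon blind spot
        return ("na",)
    raise AssertionError(st)


def simulate_population(array: TandemArrayModel, config: SimulationConfig,
                        seed: int) -> list[LineRecord]:
    """Simulate ``config.n_lines`` edited lines with ground truth."""
    rng = np.random.default_rng(seed)
    lines = []
    for i in range(config.n_lines):
        line_id = f"L{i + 1:02d}"
        events = _sample_events(array, config, rng)
        arch = AlleleArchitecture.identity(array, MAIN_CONTIG)
        for ev in events:
            arch = apply_event(arch, ev, array)
        calls = gene_states(arch, array)
        truth = TruthRecord(
            line_id=line_id,
            calls=calls,
            events=events,
            junctions=junction_set(arch, array),
            expected_amplicon={gid: expected_amplicon_call(c, array)
                               for gid, c in calls.items()},
        )
        lines.append(LineRecord(line_id, arch, truth))
    return lines


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def line_genome(line: LineRecord, array: TandemArrayModel) -> dict[str, str]:
    """All molecules present in a line's nucleus (hemizygous model):
    the edited main contig plus the unedited sibling and homoeologous contigs."""
    edited = render_sequence(line.architecture, array)
    genome = {MAIN_CONTIG: edited}
    for name, seq in array.contigs.items():
        if name != MAIN_CONTIG:
            genome[name] = seq
    return genome


@dataclass(frozen=True)
class ReadPair:
    read_id: str
    r1: str
    r2: str


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    for i in np.nonzero(rng.random(len(seq)) < rate)[0]:
        out[i] = BASES[(BASES.index(out[i]) + 1 + rng.integers(3)) % 4]
    return "".join(out)


def simulate_amplicon_reads(genome: dict[str, str], products, depth: int,
                            config: SimulationConfig,
                            seed: int = 0) -> list[ReadPair]:
    """PE150 amplicon reads from predicted PCR products.

    Reads are exact substrings of each product; each short product receives
    ``depth`` identical pairs (products are clonal), long products (>400 bp,
    disfavoured by short-cycle PCR) receive depth/20.  No product, no reads:
    that is the NA mechanism.
    """
    rng = np.random.default_rng(seed)
    reads = []
    n = 0
    for prod in products:
        seq = prod.seq
        weight = depth if len(seq) <= 400 else max(1, depth // 20)
        r1 = seq[:config.read_len]
        r2 = revcomp(seq)[:config.read_len]
        for _ in range(weight):
            reads.append(ReadPair(
                f"amp_{n}_{prod.molecule}_{prod.start}",
                _apply_errors(r1, config.error_rate, rng),
                _apply_errors(r2, config.error_rate, rng)))
            n += 1
    return reads


def capture_identity(array: TandemArrayModel, probe_gene: str = "g7",
                     window: int = 100) -> dict[str, np.ndarray]:
    """Per-base probe-homology identity along each reference contig.

    For every locus, the best ungapped offset alignment against the probe
    source gene is found and per-base equality is smoothed over
    ``window``-bp probe windows.  Intergenic sequence scores zero.
    """
    probe = array.gene_sequence(probe_gene)
    out = {}
    kernel = np.ones(window) / window
    for contig, seq in array.contigs.items():
        ident = np.zeros(len(seq))
        for locus in array.genes_on(contig):
            lseq = array.gene_sequence(locus.id)
            la = np.frombuffer(lseq.encode(), dtype=np.uint8)
            pa = np.frombuffer(probe.encode(), dtype=np.uint8)
            if len(la) > len(pa):
                continue
            best_off, best_eq = 0, None
            step = 1 if len(pa) - len(la) < 1200 else 2
            for off in range(0, len(pa) - len(la) + 1, step):
                eq = la == pa[off:off + len(la)]
                if best_eq is None or eq.sum() > best_eq.sum():
                    best_off, best_eq = off, eq
            smooth = np.convolve(best_eq.astype(float), kernel, mode="same")
            # map transcription coords back to axis
            axis = smooth[::-1] if locus.strand == "-" else smooth
            ident[locus.start:locus.end] = axis
        out[contig] = ident
    return out


def _arch_identity(arch: AlleleArchitecture, ident: dict[str, np.ndarray],
                   array: TandemArrayModel) -> np.ndarray:
    parts = []
    for i, seg in enumerate(arch.segments):
        a = ident[seg.contig][seg.start:seg.end]
        if seg.orient == "-":
            a = a[::-1]
        a = a.copy()
        for off, e in sorted(arch._segment_edits(i), reverse=True):
            if e.indel_size > 0:
                val = 1.0 if e.insert_source else 0.0
                a = np.concatenate([a[:off], np.full(e.indel_size, val), a[off:]])
            else:
                a = np.concatenate([a[:off], a[off - e.indel_size:]])
        parts.append(a)
    return np.concatenate(parts) if parts else np.zeros(0)


def simulate_capture_reads(genome: dict[str, str], arch: AlleleArchitecture,
                           array: TandemArrayModel, depth: float,
                           config: SimulationConfig, seed: int = 0,
                           probe_gene: str = "g7") -> list[ReadPair]:
    """PE150 capture reads from ~Normal(550, 60) fragments.

    A fragment is retained with probability equal to its best probe-window
    identity when that identity clears the capture threshold (default
    0.85), else with the off-target background rate.  ``depth`` is the
    approximate read coverage over probe-homologous regions.
    """
    if depth <= 0:
        return []
    rng = np.random.default_rng(seed)
    ident = capture_identity(array, probe_gene)
    weight = {MAIN_CONTIG: _arch_identity(arch, ident, array)}
    for name in genome:
        if name != MAIN_CONTIG:
            weight[name] = ident[name]
    thr = config.capture_identity_threshold
    l_cap = sum(int((w >= thr).sum()) for w in weight.values())
    target = int(depth * l_cap / (2 * config.read_len))
    names = sorted(genome)
    lens = np.array([len(genome[n]) for n in names], dtype=float)
    mol_p = lens / lens.sum()

    reads = []
    trials = 0
    max_trials = 80 * max(target, 1)
    while len(reads) < target and trials < max_trials:
        trials += 1
        mi = int(rng.choice(len(names), p=mol_p))
        mol = names[mi]
        seq = genome[mol]
        flen = int(np.clip(rng.normal(config.insert_mean, config.insert_sd),
                           2 * config.read_len + 20, len(seq)))
        if len(seq) <= flen:
            continue
        s = int(rng.integers(0, len(seq) - flen))
        wmax = float(weight[mol][s:s + flen].max(initial=0.0))
        p = wmax if wmax >= thr else config.capture_background
        if rng.random() >= p:
            continue
        frag = seq[s:s + flen]
        r1 = _apply_errors(frag[:config.read_len], config.error_rate, rng)
        r2 = _apply_errors(revcomp(frag)[:config.read_len],
                           config.error_rate, rng)
        reads.append(ReadPair(f"cap_{len(reads)}_{mol}_{s}_{flen}", r1, r2))
    return reads
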