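"""Integrate amplicon calls, PCR predictions, and capture evidence into
per-line allele architectures.

The reconstructor enumerates short ordered sequences of structural events
(dropouts, local deletions, inversions, translocations, templated-insert
fusions) whose forward-simulated junction sets explain the observed
junction evidence.  Breakpoints are restricted to guide cut points of
evidence-implicated loci plus evidence-implied non-cut offsets, and the
search depth is capped (default 3 events): unbounded search is exponential
and observed mutant complexity fits within three events.

Scenarios are scored as |predicted junction set Δ observed| plus a
parsimony penalty of 0.5 per event; ties are reported, never silently
broken.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx

from .amplicon import AlleleCall
from .capture import CaptureEvidence, DiscordantCluster
from .model import (
    AlleleArchitecture,
    EditEvent,
    EditConflictError,
    Junction,
    StaleBreakpointError,
    TandemArrayModel,
    TruthCall,
    apply_event,
    gene_states,
    junction_set,
    render_sequence,
    revcomp,
)
from .simulate import AmpliconLayout, expected_amplicon_call

__all__ = [
    "EventScenario",
    "ScenarioResult",
    "build_junction_graph",
    "observed_signatures",
    "infer_events",
    "candidate_events",
    "reconcile",
    "dropout_size",
    "GeneReport",
]

LOCAL_DELETION_SPAN = 2500  # same-gene two-breakpoint deletions below this
PARSIMONY_LAMBDA = 0.5


# ---------------------------------------------------------------------------
# Junction graph
# ---------------------------------------------------------------------------

def build_junction_graph(amplicon_calls: Iterable[AlleleCall],
                         junctions: Iterable[Junction],
                         clusters: Iterable[DiscordantCluster],
                         array: TandemArrayModel,
                         layout: AmpliconLayout = AmpliconLayout()
                         ) -> nx.MultiDiGraph:
    """Evidence-weighted joint graph: nodes are loci, edges are joints.

    Black (known) edges come from amplicon fusion calls and assembled or
    read-voted capture junctions; unassembled discordant clusters become
    gray edges (``known=False``) that contribute breakpoint hints but no
    observed junction signature.
    """
    g = nx.MultiDiGraph()
    for call in amplicon_calls:
        if call.category != "fusion" or not call.fusion_id:
            continue
        if "-" not in call.fusion_id:
            continue
        a, b = call.fusion_id.split("-", 1)
        if call.gene_id != a:
            continue  # the linked pair is recorded once, on its 5' gene
        key = f"amp:{call.fusion_id}"
        if g.has_edge(a, b, key=key):
            continue
        g.add_edge(a, b, key=key, orientation="productive",
                   provenance="amplicon", support=call.count,
                   t5=layout.cut, t3=layout.cut, net_indel=call.indel,
                   inserted=getattr(call, "inserted", ""), known=True)
    for j in junctions:
        key = f"{j.provenance}:{j.side5[0]}:{j.side3[0]}:{j.side5[1]}"
        g.add_edge(j.side5[0], j.side3[0], key=key,
                   orientation=j.orientation, provenance=j.provenance,
                   support=0, t5=j.side5[1], t3=j.side3[1],
                   net_indel=j.net_indel, inserted=j.inserted,
                   insert_source=j.insert_source, known=True)
    for i, cl in enumerate(clusters):
        loci = list(cl.loci)
        if len(loci) >= 2:
            g.add_edge(loci[0], loci[-1], key=f"gray:{i}",
                       orientation="unknown", provenance="read_pair",
                       support=cl.support, known=False)
    return g


def _edge_signature(u: str, v: str, data: dict) -> Optional[tuple]:
    if not data.get("known"):
        return None
    if data["orientation"] == "productive":
        return ("P", u, v)
    if data["orientation"] == "opposing":
        pair = tuple(sorted((u, v)))
        return ("O", pair[0], pair[1])
    return None


def observed_signatures(graph: nx.MultiDiGraph) -> frozenset:
    sigs = set()
    for u, v, data in graph.edges(data=True):
        s = _edge_signature(u, v, data)
        if s is not None:
            sigs.add(s)
    return frozenset(sigs)


# ---------------------------------------------------------------------------
# Scenario search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EventScenario:
    events: tuple[EditEvent, ...]
    predicted: frozenset
    mismatch: int
    score: float
    offset_penalty: int = 0  # bp disagreement with evidence joint offsets

    @property
    def n_events(self) -> int:
        return len(self.events)


@dataclass
class ScenarioResult:
    scenarios: list[EventScenario]       # all mismatch-0, or best few
    observed: frozenset
    unexplained: frozenset = frozenset() # observed sigs no scenario covers
    exhaustive: bool = True

    @property
    def best(self) -> Optional[EventScenario]:
        return self.scenarios[0] if self.scenarios else None

    @property
    def ties(self) -> list[EventScenario]:
        if not self.scenarios:
            return []
        top = self.scenarios[0].score
        return [s for s in self.scenarios if s.score == top]


def _deletion_kind(array: TandemArrayModel, pos_a: int, pos_b: int,
                   contig: str) -> str:
    la, _ = array.locus_at(contig, pos_a)
    lb, _ = array.locus_at(contig, pos_b)
    if la.id == lb.id and pos_b - pos_a <= LOCAL_DELETION_SPAN:
        return "local_deletion"
    return "dropout_fusion"


def candidate_events(graph: nx.MultiDiGraph, array: TandemArrayModel,
                     main_contig: str = "chr10",
                     with_alternatives: bool = False):
    """Events worth trying: breakpoints are cut points of evidence loci plus
    evidence-implied non-cut offsets; translocations and templated inserts
    are instantiated directly from the edges that imply them.

    Joint offsets within the microhomology drift of a cut are snapped to the
    cut for the search; the raw offsets are kept as refinement alternatives.
    """
    breakpoints: set[int] = set()
    raw_alternatives: dict[int, set[int]] = {}
    events: list[EditEvent] = []
    snap = 110  # microhomology can drift a joint this far from the true cut
    for u, v, data in graph.edges(data=True):
        for locus_id, t in ((u, data.get("t5")), (v, data.get("t3"))):
            try:
                locus = array.gene(locus_id)
            except KeyError:
                continue
            if locus.contig != main_contig or locus.is_pseudogene:
                continue
            if locus.cut_point is not None:
                breakpoints.add(locus.cut_point)
            if t is not None:
                b = locus.t_to_axis(t)
                if locus.cut_point is None or abs(b - locus.cut_point) > snap:
                    breakpoints.add(b)
                elif abs(b - locus.cut_point) > 2:
                    raw_alternatives.setdefault(
                        locus.cut_point, set()).add(b)
        # interchromosomal edge -> translocation candidate
        sides = [(u, data.get("t5")), (v, data.get("t3"))]
        part = [(lid, t) for lid, t in sides
                if lid in {x.id for x in array.genes}
                and array.gene(lid).contig != main_contig]
        host = [(lid, t) for lid, t in sides
                if lid in {x.id for x in array.genes}
                and array.gene(lid).contig == main_contig
                and not array.gene(lid).is_pseudogene]
        if part and host and data.get("known"):
            (plid, pt), (hlid, ht) = part[0], host[0]
            partner_locus = array.gene(plid)
            host_locus = array.gene(hlid)
            hb = host_locus.t_to_axis(ht) if ht is not None \
                else host_locus.cut_point
            if host_locus.cut_point is not None \
                    and abs(hb - host_locus.cut_point) <= snap:
                hb = host_locus.cut_point
            pb = partner_locus.t_to_axis(pt) if pt is not None \
                else (partner_locus.start + partner_locus.end) // 2
            events.append(EditEvent("translocation", (hb,), main_contig,
                                    partner=(partner_locus.contig, pb, "+")))
        # templated insert -> insert-carrying deletion between the sides
        if data.get("known") and data.get("inserted") \
                and data.get("insert_source"):
            try:
                def snapped(gid, t):
                    loc = array.gene(gid)
                    b = loc.t_to_axis(t)
                    if loc.cut_point is not None \
                            and abs(b - loc.cut_point) <= snap:
                        return loc.cut_point
                    return b
                b5 = snapped(u, data["t5"])
                b3 = snapped(v, data["t3"])
            except KeyError:
                b5 = b3 = None
            if b5 is not None and b3 is not None and b5 != b3 \
                    and array.gene(u).contig == main_contig \
                    and array.gene(v).contig == main_contig:
                a, b = sorted((b5, b3))
                events.append(EditEvent(
                    "templated_insert_fusion", (a, b), main_contig,
                    insert_source=data["insert_source"]))

    # inversions are only worth trying when something opposing-like was seen
    need_inversions = any(
        data.get("orientation") == "opposing"
        or (not data.get("known")
            and data.get("orientation") in ("unknown",))
        for _, _, data in graph.edges(data=True))
    bps = sorted(breakpoints)
    for a, b in itertools.combinations(bps, 2):
        kind = _deletion_kind(array, a, b, main_contig)
        events.append(EditEvent(kind, (a, b), main_contig))
        if need_inversions:
            events.append(EditEvent("inversion", (a, b), main_contig))
    if with_alternatives:
        return events, raw_alternatives
    return events


def infer_events(graph: nx.MultiDiGraph, array: TandemArrayModel,
                 d_max: int = 3, lam: float = PARSIMONY_LAMBDA,
                 main_contig: str = "chr10",
                 max_expansions: int = 200_000) -> ScenarioResult:
    """Breadth-limited enumeration of event sequences scored against the
    observed junction signatures.

    All mismatch-0 scenarios are returned sorted by (score, event count,
    representation); when none exists the best-scoring few are returned
    along with the orphan signatures (the "unexplained" report).
    """
    observed = observed_signatures(graph)
    identity = AlleleArchitecture.identity(array, main_contig)
    if not observed:
        return ScenarioResult(
            [EventScenario((), frozenset(), 0, 0.0)], observed)

    cands, raw_alts = candidate_events(graph, array, main_contig,
                                       with_alternatives=True)
    scenarios: list[EventScenario] = []
    expansions = 0
    exhaustive = True

    # observed joint offsets break ties between signature-equivalent
    # scenarios (a joint 120 bp upstream of the cut is not the cut)
    obs_off: dict[tuple, tuple[int, int]] = {}
    for u, v, data in graph.edges(data=True):
        s = _edge_signature(u, v, data)
        if s is not None and s not in obs_off and data.get("t5") is not None:
            obs_off[s] = (data["t5"], data["t3"])

    def offset_penalty(juncs) -> int:
        pen = 0
        for j in juncs:
            o = obs_off.get(j.signature())
            if o is None:
                continue
            if j.orientation == "productive":
                pen += abs(j.side5[1] - o[0]) + abs(j.side3[1] - o[1])
            else:
                a = sorted((j.side5[1], j.side3[1]))
                b = sorted(o)
                pen += abs(a[0] - b[0]) + abs(a[1] - b[1])
        return pen

    def state_key(arch: AlleleArchitecture) -> tuple:
        segs = tuple((s.contig, s.start, s.end, s.orient)
                     for s in arch.segments)
        edits = tuple(sorted((e.contig, e.pos, e.indel_size, e.inserted_seq)
                             for e in arch.inline_edits))
        return segs, edits

    # breadth-first so the shortest event sequence claims each architecture;
    # event orderings that reach the same architecture are one scenario
    # (their junction sets are equal) and are pruned by visited-state dedup
    from collections import deque
    visited: set[tuple] = {state_key(identity)}
    queue: deque[tuple[AlleleArchitecture, tuple[EditEvent, ...]]] = \
        deque([(identity, ())])
    while queue:
        arch, events = queue.popleft()
        if len(events) >= d_max:
            continue
        for ev in cands:
            expansions += 1
            if expansions > max_expansions:
                exhaustive = False
                break
            try:
                new = apply_event(arch, ev, array)
            except (StaleBreakpointError, EditConflictError, ValueError):
                continue
            key = state_key(new)
            if key in visited:
                continue
            visited.add(key)
            seq = events + (ev,)
            juncs = junction_set(new, array)
            pred = frozenset(j.signature() for j in juncs)
            mismatch = len(pred ^ observed)
            scenarios.append(EventScenario(
                seq, pred, mismatch, mismatch + lam * len(seq),
                offset_penalty(juncs)))
            # a perfect state needs no elaboration: any further event adds
            # junctions and breaks the explanation again
            if mismatch > 0:
                queue.append((new, seq))
        if not exhaustive:
            break

    def sort_key(s: EventScenario):
        return (s.score, s.n_events, s.offset_penalty, repr(s.events))

    def refine(s: EventScenario) -> EventScenario:
        """Local search: substitute raw evidence offsets for snapped cut
        breakpoints where that lowers the offset disagreement."""
        if not raw_alts or s.offset_penalty == 0:
            return s
        import itertools as it
        options = []
        for ev in s.events:
            alts = [ev]
            if len(ev.breakpoints) == 2:
                a, b = ev.breakpoints
                for a2 in sorted({a} | raw_alts.get(a, set())):
                    for b2 in sorted({b} | raw_alts.get(b, set())):
                        if (a2, b2) != (a, b) and a2 < b2:
                            alts.append(EditEvent(
                                ev.kind, (a2, b2), ev.contig, ev.indel_size,
                                ev.inserted_seq, ev.insert_source, ev.partner))
            options.append(alts[:6])
        best = s
        combos = it.islice(it.product(*options), 200)
        for combo in combos:
            if tuple(combo) == s.events:
                continue
            arch = AlleleArchitecture.identity(array, main_contig)
            try:
                for ev in combo:
                    arch = apply_event(arch, ev, array)
            except (StaleBreakpointError, EditConflictError, ValueError):
                continue
            juncs = junction_set(arch, array)
            pred = frozenset(j.signature() for j in juncs)
            if pred != s.predicted:
                continue
            pen = offset_penalty(juncs)
            if pen < best.offset_penalty:
                best = EventScenario(tuple(combo), pred, s.mismatch, s.score,
                                     pen)
        return best

    scenarios.sort(key=sort_key)
    perfect = [s for s in scenarios if s.mismatch == 0]
    if perfect:
        refined = [refine(s) for s in perfect[:5]] + perfect[5:]
        refined.sort(key=sort_key)
        # keep the originals too when refinement changed them: ties are
        # reported, never silently replaced
        seen_events = {s.events for s in refined}
        for s in perfect[:5]:
            if s.events not in seen_events:
                refined.append(s)
        refined.sort(key=sort_key)
        return ScenarioResult(refined, observed, frozenset(), exhaustive)
    best = scenarios[:10]
    covered = frozenset().union(*(s.predicted for s in best)) if best \
        else frozenset()
    return ScenarioResult(best, observed, observed - covered, exhaustive)


# ---------------------------------------------------------------------------
# Reconciliation
# ---------------------------------------------------------------------------

CONFLICT_CODES = ("AMPLICON_BLINDSPOT", "PRIMER_SITE_LOST",
                  "AMBIGUOUS_PARALOG", "UNEXPLAINED_JUNCTION")


@dataclass
class GeneReport:
    gene_id: str
    final: TruthCall
    amplicon_category: Optional[str]
    consistent: bool
    conflicts: tuple[str, ...] = ()


def _project(call: TruthCall, array: TandemArrayModel,
             layout: AmpliconLayout) -> tuple:
    return expected_amplicon_call(call, array, layout)


def reconcile(line_id: str, amplicon_calls: list[AlleleCall],
              banding_na: Optional[list[str]],
              evidence: Optional[CaptureEvidence],
              result: ScenarioResult, array: TandemArrayModel,
              layout: AmpliconLayout = AmpliconLayout(),
              main_contig: str = "chr10") -> list[GeneReport]:
    """Final per-gene report: scenario-implied state with conflict flags.

    The scenario is the arbiter; disagreements with the amplicon layer are
    annotated with an explanation code rather than suppressed.
    """
    best = result.best
    arch = AlleleArchitecture.identity(array, main_contig)
    if best is not None:
        for ev in best.events:
            arch = apply_event(arch, ev, array)
    # amplicon-detected cut-site indels are part of the final architecture
    amp_by_gene = {c.gene_id: c for c in amplicon_calls}
    for gid, call in amp_by_gene.items():
        if call.category == "indel":
            g = array.gene(gid)
            try:
                ins = "N" * call.indel if call.indel > 0 else ""
                arch = apply_event(
                    arch, EditEvent("small_indel", (g.cut_point,),
                                    main_contig, call.indel, ins), array)
            except (StaleBreakpointError, EditConflictError):
                pass
    final_states = gene_states(arch, array, main_contig)
    rendered_best = render_sequence(arch, array)

    unexplained_loci = {l for sig in result.unexplained for l in sig[1:3]}
    reports = []
    for g in array.array_genes():
        state = final_states[g.id]
        amp = amp_by_gene.get(g.id)
        amp_cat = amp.category if amp else None
        expected = _project(state, array, layout)
        got = None
        if amp is not None:
            got = {"native": ("native",), "na": ("na",),
                   "no_call": ("na",)}.get(amp.category)
            if got is None:
                got = (("indel", amp.indel) if amp.category == "indel"
                       else ("fusion", amp.fusion_id, amp.indel))
        conflicts = []
        agree = (got is None) or (got == expected) or \
            (got[0] == expected[0] == "fusion")
        if amp_cat in ("native", "indel") \
                and state.state in ("fusion_3", "fusion_5", "translocated"):
            # the gene is fused, yet its native amplicon window survives
            # verbatim in the reconstructed sequence: the joint lies outside
            # the amplicon and the amplicon layer cannot see it
            window = array.gene_sequence(g.id)[layout.start:layout.end]
            if window in rendered_best or revcomp(window) in rendered_best:
                conflicts.append("AMPLICON_BLINDSPOT")
        if amp_cat in ("na", "no_call") and state.state in (
                "indel", "native", "inverted"):
            # gene present per the scenario but silent on the amplicon:
            # a primer-binding site was lost (or the product got too long)
            conflicts.append("PRIMER_SITE_LOST")
        if amp is not None and "ambiguous" in amp.flags:
            if not (best is not None and best.mismatch == 0):
                conflicts.append("AMBIGUOUS_PARALOG")
        if g.id in unexplained_loci:
            conflicts.append("UNEXPLAINED_JUNCTION")
        reports.append(GeneReport(g.id, state, amp_cat,
                                  agree and not conflicts,
                                  tuple(conflicts)))
    return reports


def dropout_size(event: EditEvent, array: TandemArrayModel) -> int:
    """Net base pairs removed by a two-breakpoint deletion event."""
    if event.kind not in ("dropout_fusion", "local_deletion",
                          "templated_insert_fusion"):
        raise ValueError(f"{event.kind} has no dropout size")
    ins = len(event.inserted_seq)
    if event.kind == "templated_insert_fusion" and event.insert_source:
        ins = event.insert_source[2]
    pos_a, pos_b = event.breakpoints
    return pos_b - pos_a - ins
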