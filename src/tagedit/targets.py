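"""Amplicon reference construction: native targets plus all hypothetical
fusion targets between sequential (adjacent or nonadjacent) paralogs.

A fusion target ``A-B`` is the 5' side of A's amplicon up to A's cut joined
to the 3' side of B's amplicon from B's cut.  Only productive-orientation
fusions are enumerated: opposing joints cannot amplify with a convergent
primer pair.  Targets with identical sequences are merged into ambiguity
classes that propagate to allele calling rather than being broken
arbitrarily.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .model import TandemArrayModel
from .pcr import PrimerPair

__all__ = ["AmpliconTarget", "TargetSet", "enumerate_targets"]


@dataclass(frozen=True)
class AmpliconTarget:
    id: str
    ids: tuple[str, ...]            # all members of the ambiguity class
    sequence: str
    primer_pair: str
    cut: int                        # cut/joint offset in target coordinates
    components: tuple[str, ...]     # ("g3",) native or ("g7", "g2") fusion
    distinguishing: tuple[int, ...] = ()

    @property
    def is_fusion(self) -> bool:
        return len(self.components) == 2

    @property
    def ambiguous(self) -> bool:
        return len(self.ids) > 1


@dataclass
class TargetSet:
    targets: list[AmpliconTarget]
    warnings: list[str] = field(default_factory=list)
    n_before_dedupe: int = 0

    def by_sequence(self) -> dict[str, AmpliconTarget]:
        return {t.sequence: t for t in self.targets}

    def get(self, target_id: str) -> AmpliconTarget:
        for t in self.targets:
            if target_id in t.ids:
                return t
        raise KeyError(target_id)


def _native_window(array: TandemArrayModel, gene_id: str,
                   pair: PrimerPair) -> Optional[tuple[str, int, int]]:
    """(amplicon sequence, window start t, cut offset) or None if a primer
    has no exact site on the gene."""
    g = array.gene(gene_id)
    seq = array.gene_sequence(gene_id)
    f = seq.find(pair.fwd)
    from .model import revcomp
    r = seq.find(revcomp(pair.rev))
    if f < 0 or r < 0 or not f < r:
        return None
    end = r + len(pair.rev)
    if g.cut_point is None:
        cut = -1
    else:
        t_cut = g.axis_to_t(g.cut_point)
        if not f < t_cut < end:
            return None
        cut = t_cut - f
    return seq[f:end], f, cut


def enumerate_targets(array: TandemArrayModel, pair: PrimerPair,
                      genes_subset: Optional[list[str]] = None,
                      control_locus: Optional[str] = "c8.1p") -> TargetSet:
    """Native + n(n-1) ordered fusion targets, deduplicated by sequence.

    Genes missing a primer site are omitted with a warning record.  The
    control locus (a nontarget pseudogene amplified by the same pair)
    contributes a native target only.
    """
    gene_ids = genes_subset or [g.id for g in array.array_genes()]
    windows: dict[str, tuple[str, int, int]] = {}
    warnings: list[str] = []
    for gid in gene_ids:
        w = _native_window(array, gid, pair)
        if w is None:
            warnings.append(f"{gid}: no exact primer site; targets omitted")
        else:
            windows[gid] = w

    raw: list[tuple[str, str, int, tuple[str, ...]]] = []
    for gid, (seq, _, cut) in windows.items():
        raw.append((gid, seq, cut, (gid,)))
    for a, (sa, _, ca) in windows.items():
        for b, (sb, _, cb) in windows.items():
            if a == b:
                continue
            raw.append((f"{a}-{b}", sa[:ca] + sb[cb:], ca, (a, b)))
    n_before = len(raw)

    if control_locus is not None:
        w = _native_window(array, control_locus, pair)
        if w is None:
            warnings.append(f"{control_locus}: control locus does not amplify")
        else:
            seq, _, _ = w
            raw.append((control_locus, seq, -1, (control_locus,)))

    # dedupe on full sequence -> ambiguity classes
    by_seq: dict[str, list[tuple[str, int, tuple[str, ...]]]] = {}
    order: list[str] = []
    for tid, seq, cut, comp in raw:
        if seq not in by_seq:
            order.append(seq)
        by_seq.setdefault(seq, []).append((tid, cut, comp))

    merged: list[AmpliconTarget] = []
    for seq in order:
        members = by_seq[seq]
        ids = tuple(m[0] for m in members)
        tid, cut, comp = members[0]
        merged.append(AmpliconTarget(tid, ids, seq, pair.id, cut, comp))

    # distinguishing positions among equal-length target sequences
    by_len: dict[int, list[AmpliconTarget]] = {}
    for t in merged:
        by_len.setdefault(len(t.sequence), []).append(t)
    final = []
    for t in merged:
        peers = [o for o in by_len[len(t.sequence)] if o is not t]
        if peers:
            dist = tuple(i for i, base in enumerate(t.sequence)
                         if all(o.sequence[i] != base for o in peers))
        else:
            dist = tuple()
        final.append(AmpliconTarget(t.id, t.ids, t.sequence, t.primer_pair,
                                    t.cut, t.components, dist))
    return TargetSet(final, warnings, n_before)
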