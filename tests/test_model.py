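"""Forward model: loci, guide validation, events, rendering, junctions."""

import pytest
from hypothesis import given, strategies as st

from tagedit.model import (
    AlleleArchitecture,
    EditEvent,
    GeneLocus,
    GuideDesign,
    Junction,
    StaleBreakpointError,
    TandemArrayModel,
    apply_event,
    frame_status,
    gene_states,
    junction_set,
    render_sequence,
    revcomp,
    validate_guide,
)


# ---------------------------------------------------------------------------
# Type invariants
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("kwargs", [
    dict(id="x", interval=(10, 10), strand="-", cut_point=None,
         is_pseudogene=True),                       # empty interval
    dict(id="x", interval=(0, 100), strand="-", cut_point=150),  # cut outside
    dict(id="x", interval=(0, 100), strand="-", cut_point=50,
         is_pseudogene=True),                       # pseudogene with cut
    dict(id="x", interval=(0, 100), strand="-", cut_point=None),  # gene w/o cut
])
def test_locus_invariants_rejected(kwargs):
    with pytest.raises(ValueError):
        GeneLocus(**kwargs)


def test_guide_design_rejects_bad_spacer():
    with pytest.raises(ValueError):
        GuideDesign(spacer="ACGTNACGTACGTACGTACG")
    with pytest.raises(ValueError):
        GuideDesign(spacer="ACGT" * 5, cut_offset=25)


# ---------------------------------------------------------------------------
# Guide validation
# ---------------------------------------------------------------------------

def test_guide_hits_all_genes_and_no_pseudogenes(array):
    reports = validate_guide(array)
    genes = [r for r in reports if not r.is_pseudogene]
    pseudos = [r for r in reports if r.is_pseudogene]
    assert len(genes) == 7 and all(r.n_matches == 1 for r in genes)
    assert len(pseudos) == 4 and all(r.n_matches == 0 for r in pseudos)
    assert not any(r.violation for r in reports)


def test_guide_snp_in_spacer_flags_violation(array):
    g1 = array.gene("g1")
    pos = g1.cut_point + 5  # inside the protospacer on the axis
    seq = array.contigs[g1.contig]
    base = seq[pos]
    new = seq[:pos] + ("A" if base != "A" else "C") + seq[pos + 1:]
    mutated = TandemArrayModel({**array.contigs, g1.contig: new},
                               array.genes, array.guide,
                               array.diagnostic_variants)
    reports = {r.locus_id: r for r in validate_guide(mutated)}
    assert reports["g1"].n_matches == 0 and reports["g1"].violation
    assert not reports["g2"].violation


# ---------------------------------------------------------------------------
# Events, rendering, arithmetic
# ---------------------------------------------------------------------------

def test_identity_renders_reference(array):
    arch = AlleleArchitecture.identity(array)
    assert render_sequence(arch, array) == array.contigs["chr10"]
    assert junction_set(arch, array) == []


def test_dropout_length_arithmetic(array):
    arch = AlleleArchitecture.identity(array)
    ev = EditEvent("dropout_fusion", (12_000, 89_000))
    out = apply_event(arch, ev, array)
    ref_len = len(array.contigs["chr10"])
    assert len(render_sequence(out, array)) == ref_len - 77_000


def test_templated_insert_reduces_net_length(array, cuts):
    arch = AlleleArchitecture.identity(array)
    ev = EditEvent("templated_insert_fusion", (cuts["g2"], cuts["g7"]),
                   insert_source=("g5", 837, 80))
    out = apply_event(arch, ev, array)
    removed = cuts["g7"] - cuts["g2"] - 80
    ref_len = len(array.contigs["chr10"])
    assert len(render_sequence(out, array)) == ref_len - removed
    (j,) = junction_set(out, array)
    assert j.inserted == array.gene_sequence("g5")[837:917]
    assert j.net_indel == 80


def test_inversion_conserves_length_and_composition(array, cuts):
    """An inversion reverse-complements a block in place: the length and the
    strand-symmetric base composition (A+T, C+G counts) are conserved."""
    arch = AlleleArchitecture.identity(array)
    out = apply_event(arch, EditEvent("inversion", (cuts["g2"], cuts["g6"])),
                      array)
    ref = array.contigs["chr10"]
    rendered = render_sequence(out, array)
    assert len(rendered) == len(ref)

    def symm(s):
        return (s.count("A") + s.count("T"), s.count("C") + s.count("G"))

    assert symm(rendered) == symm(ref)
    # and the duplex (sequence plus its reverse complement) is base-for-base
    # conserved
    assert sorted(rendered + revcomp(rendered)) == sorted(ref + revcomp(ref))


def test_double_inversion_identical_breakpoints_is_identity(array, cuts):
    arch = AlleleArchitecture.identity(array)
    ev = EditEvent("inversion", (cuts["g3"], cuts["g5"]))
    out = apply_event(apply_event(arch, ev, array), ev, array)
    assert render_sequence(out, array) == array.contigs["chr10"]
    assert junction_set(out, array) == []


def test_stale_breakpoint_raises(array, cuts):
    arch = apply_event(AlleleArchitecture.identity(array),
                       EditEvent("dropout_fusion", (cuts["g2"], cuts["g6"])),
                       array)
    with pytest.raises(StaleBreakpointError):
        apply_event(arch, EditEvent("small_indel", (cuts["g4"],),
                                    indel_size=-2), array)


@given(st.integers(5_000, 40_000), st.integers(45_000, 95_000),
       st.integers(0, 30))
def test_dropout_removes_exactly_the_interval(array, a, b, ins_len):
    arch = AlleleArchitecture.identity(array)
    ev = EditEvent("dropout_fusion", (a, b), inserted_seq="A" * ins_len)
    out = apply_event(arch, ev, array)
    expected = len(array.contigs["chr10"]) - (b - a) + ins_len
    assert len(render_sequence(out, array)) == expected


@given(st.integers(5_000, 45_000), st.integers(50_000, 95_000))
def test_inversion_involution(array, a, b):
    arch = AlleleArchitecture.identity(array)
    ev = EditEvent("inversion", (a, b))
    out = apply_event(apply_event(arch, ev, array), ev, array)
    assert out.segments != [] and \
        render_sequence(out, array) == array.contigs["chr10"]


# ---------------------------------------------------------------------------
# Junctions and fusion naming
# ---------------------------------------------------------------------------

def test_dropout_junction_names_5prime_partner_first(array, cuts):
    """Genes sit on the minus strand of the axis, so deleting between the
    cuts of g2 and g7 fuses 5'-g7 to 3'-g2 and drops g3..g6."""
    arch = apply_event(AlleleArchitecture.identity(array),
                       EditEvent("dropout_fusion", (cuts["g2"], cuts["g7"])),
                       array)
    (j,) = junction_set(arch, array)
    assert j.orientation == "productive"
    assert j.side5 == ("g7", 917) and j.side3 == ("g2", 917)
    states = gene_states(arch, array)
    assert all(states[g].state == "absent" for g in ("g3", "g4", "g5", "g6"))
    assert states["g7"].state == "fusion_5"
    assert states["g2"].state == "fusion_3"


def test_single_event_junction_cardinality(array, cuts):
    base = AlleleArchitecture.identity(array)
    drop = apply_event(base, EditEvent(
        "dropout_fusion", (cuts["g3"], cuts["g5"])), array)
    assert len(junction_set(drop, array)) == 1
    inv = apply_event(base, EditEvent(
        "inversion", (cuts["g3"], cuts["g5"])), array)
    assert len(junction_set(inv, array)) == 2
    tr = apply_event(base, EditEvent(
        "translocation", (cuts["g7"],),
        partner=("chr10_short", 11_000, "+")), array)
    assert len(junction_set(tr, array)) == 1
    assert junction_set(tr, array)[0].side3[0] == "g7" or \
        junction_set(tr, array)[0].side5[0] == "g7"


# --- independent oracle: segment a rendered sequence against the reference
#     by greedy maximal exact matching and count the switches -----------------

def _oracle_blocks(rendered: str, ref: str, k: int = 31):
    """Brute-force segmentation: from each position, take the longest exact
    match against the reference (either strand, all occurrences) and jump to
    its end.  The number of blocks minus one is the junction count."""
    rc = revcomp(ref)
    blocks = 0
    pos = 0
    while pos < len(rendered) - k:
        probe = rendered[pos:pos + k]
        best = 0
        for seq in (ref, rc):
            start = seq.find(probe)
            while start >= 0:
                end = pos + k
                src = start + k
                while end < len(rendered) and src < len(seq) \
                        and rendered[end] == seq[src]:
                    end += 1
                    src += 1
                best = max(best, end - pos)
                start = seq.find(probe, start + 1)
        if best == 0:
            pos += 1
            continue
        blocks += 1
        pos += best
    return blocks


def test_double_inversion_brute_force(array, cuts):
    """The nested double inversion (cut2-cut6 then cut3-cut7) yields four
    joints, exactly one of which is the productive 5'-g7/3'-g3 fusion; the
    reverse event order does not produce that fusion."""
    base = AlleleArchitecture.identity(array)
    arch = apply_event(base, EditEvent("inversion", (cuts["g2"], cuts["g6"])),
                       array)
    arch = apply_event(arch, EditEvent("inversion", (cuts["g3"], cuts["g7"])),
                       array)
    juncs = junction_set(arch, array)
    assert len(juncs) == 4
    productive = [j for j in juncs if j.orientation == "productive"]
    g7_g3 = [j for j in productive
             if j.side5[0] == "g7" and j.side3[0] == "g3"]
    assert len(g7_g3) == 1
    # independent oracle agrees on the number of reference switches
    rendered = render_sequence(arch, array)
    blocks = _oracle_blocks(rendered, array.contigs["chr10"])
    assert blocks - 1 == len(juncs)

    # order sensitivity: reversed order has no 5'-g7/3'-g3 fusion
    rev = apply_event(base, EditEvent("inversion", (cuts["g3"], cuts["g7"])),
                      array)
    rev = apply_event(rev, EditEvent("inversion", (cuts["g2"], cuts["g6"])),
                      array)
    rev_prod = [(j.side5[0], j.side3[0])
                for j in junction_set(rev, array)
                if j.orientation == "productive"]
    assert ("g7", "g3") not in rev_prod


# ---------------------------------------------------------------------------
# Reading frame arithmetic
# ---------------------------------------------------------------------------

def test_frame_status_indels(array, cuts):
    assert frame_status(("g1", cuts["g1"], -3), array) == "in_frame"
    assert frame_status(("g1", cuts["g1"], 1), array) == "frameshift"
    assert frame_status(("g1", cuts["g1"], -20), array) == "frameshift"
    intron = array.gene("g1").t_to_axis(500)  # intron 1
    assert frame_status(("g1", intron, -3), array) == "noncoding"


def test_frame_status_fusion_junctions(array):
    j0 = Junction(("g7", 917), ("g2", 917), "productive", net_indel=0)
    assert frame_status(j0, array) == "in_frame"
    j20 = Junction(("g6", 917), ("g2", 917), "productive", net_indel=-20)
    assert frame_status(j20, array) == "frameshift"
    opp = Junction(("g2", 917), ("g6", 917), "opposing")
    assert frame_status(opp, array) == "frameshift"


def test_frame_invariant_to_indel_attribution(array, cuts):
    """A joint deletion lands the same frame class whether it is carried by
    the junction's 5' flank (axis-right of the joint) or 3' flank."""
    base = AlleleArchitecture.identity(array)
    drop = EditEvent("dropout_fusion", (cuts["g2"], cuts["g7"]))
    for side in (cuts["g7"], cuts["g2"] - 6):
        arch = apply_event(base, drop, array)
        arch = apply_event(arch, EditEvent("small_indel", (side,),
                                           indel_size=-6), array)
        (j,) = junction_set(arch, array)
        assert j.net_indel == -6
        assert frame_status(j, array) == "in_frame"
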