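"""Capture mapping, coverage dropouts, discordant pairs, junction assembly."""

import pytest

from tagedit.capture import (
    ReferenceIndex,
    collect_capture_evidence,
    coverage_profile,
    detect_discordant,
    detect_dropouts,
    map_reads,
    read_vote_junctions,
    segment_junction,
)
from tagedit.capture import _map_end, _map_end_candidates
from tagedit.model import (
    AlleleArchitecture,
    EditEvent,
    apply_event,
    gene_states,
    junction_set,
    render_sequence,
    revcomp,
)
from tagedit.simulate import LineRecord, ReadPair, TruthRecord, line_genome, simulate_capture_reads


@pytest.fixture(scope="module")
def ref(array):
    return ReferenceIndex(array.contigs)


def _line(array, arch, lid="X"):
    truth = TruthRecord(lid, gene_states(arch, array), [],
                        junction_set(arch, array), {})
    return LineRecord(lid, arch, truth)


def _evidence(array, sim_config, ref, arch, depth=30, seed=8):
    genome = line_genome(_line(array, arch), array)
    reads = simulate_capture_reads(genome, arch, array, depth, sim_config,
                                   seed=seed)
    return collect_capture_evidence(reads, array, ref), reads


# ---------------------------------------------------------------------------
# Mapper
# ---------------------------------------------------------------------------

def test_unique_read_maps_exactly(array, ref):
    g3 = array.gene("g3")
    start = g3.t_to_axis(990) - 75  # window containing a diagnostic
    read = array.contigs["chr10"][start:start + 150]
    e = _map_end(read, ref)
    assert e.contig == "chr10" and e.start == start and e.exact


def test_first_best_tie_takes_lowest_position():
    """A read from a stretch duplicated verbatim lands on the first
    (contig order, position) among tied-best placements."""
    import numpy as np
    rng = np.random.default_rng(2)
    block = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
    filler = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
    contig = filler + block + filler[::-1] + block + filler
    tie_ref = ReferenceIndex({"c1": contig})
    read = block[50:200]
    hits = _map_end_candidates(read, tie_ref)
    assert len(hits) == 2 and all(h.exact for h in hits)
    best = _map_end(read, tie_ref)
    assert best == hits[0]
    assert best.start == min(h.start for h in hits)


def test_k_larger_than_read_raises(ref):
    with pytest.raises(ValueError):
        _map_end("ACGT", ref)


def test_mapping_deterministic(array, sim_config, ref):
    arch = AlleleArchitecture.identity(array)
    genome = line_genome(_line(array, arch), array)
    reads = simulate_capture_reads(genome, arch, array, 5, sim_config, seed=3)
    a = map_reads(reads, ref)
    b = map_reads(reads, ref)
    assert a == b


def test_proper_pairs_dominate_wt(array, sim_config, ref):
    arch = AlleleArchitecture.identity(array)
    ev, reads = _evidence(array, sim_config, ref, arch, depth=10)
    classes = [a.orientation for a in ev.alignments]
    assert classes.count("FR_proper") / len(classes) > 0.95
    assert ev.clusters == [] or all(c.support < 10 for c in ev.clusters)
    assert ev.junctions == []
    assert ev.dropouts == []


# ---------------------------------------------------------------------------
# Coverage dropouts
# ---------------------------------------------------------------------------

def test_dropout_detection_spans_lost_genes(array, sim_config, ref, cuts):
    arch = apply_event(AlleleArchitecture.identity(array),
                       EditEvent("dropout_fusion", (cuts["g2"], cuts["g7"])),
                       array)
    ev, _ = _evidence(array, sim_config, ref, arch)
    assert len(ev.dropouts) == 1
    lost = set(ev.dropouts[0].genes)
    assert {"g3", "g4", "g5", "g6"} <= lost


def test_two_disjoint_dropouts_not_merged(array, sim_config, ref, cuts):
    arch = AlleleArchitecture.identity(array)
    arch = apply_event(arch, EditEvent("dropout_fusion",
                                       (cuts["g1"], cuts["g3"])), array)
    arch = apply_event(arch, EditEvent("dropout_fusion",
                                       (cuts["g5"], cuts["g7"])), array)
    ev, _ = _evidence(array, sim_config, ref, arch)
    assert len(ev.dropouts) == 2
    genes = [set(d.genes) for d in ev.dropouts]
    assert any("g2" in g for g in genes) and any("g6" in g for g in genes)


# ---------------------------------------------------------------------------
# Discordant pairs and junction evidence
# ---------------------------------------------------------------------------

def test_inversion_yields_ff_rr_clusters_and_opposing_junction(
        array, sim_config, ref, cuts):
    arch = apply_event(AlleleArchitecture.identity(array),
                       EditEvent("inversion", (cuts["g3"], cuts["g6"])),
                       array)
    ev, _ = _evidence(array, sim_config, ref, arch)
    classes = {c.orientation for c in ev.clusters}
    assert "FF" in classes or "RR" in classes
    sigs = {j.signature() for j in ev.junctions}
    assert ("O", "g3", "g6") in sigs


def test_translocation_yields_interchrom_cluster(array, sim_config, ref, cuts):
    arch = apply_event(
        AlleleArchitecture.identity(array),
        EditEvent("translocation", (cuts["g6"],),
                  partner=("chr10_short", 11_483, "+")), array)
    ev, _ = _evidence(array, sim_config, ref, arch)
    assert any(c.orientation == "interchrom" and "c10.3p" in c.loci
               for c in ev.clusters)
    assert any(j.side5[0] == "c10.3p" or j.side3[0] == "c10.3p"
               for j in ev.junctions)


def test_fusion_junction_recovered_at_cut_points(array, sim_config, ref, cuts):
    arch = apply_event(AlleleArchitecture.identity(array),
                       EditEvent("dropout_fusion", (cuts["g2"], cuts["g7"])),
                       array)
    ev, _ = _evidence(array, sim_config, ref, arch)
    assert [j.signature() for j in ev.junctions] == [("P", "g7", "g2")]
    (j,) = ev.junctions
    # microhomology may shift the reported joint; net change must be exact
    assert j.net_indel == 0


def test_templated_insert_junction_records_source(array, sim_config, ref,
                                                  cuts):
    """A three-way joint (~80 bp copied from a third paralog) is assembled
    with the inserted block and its donor recorded."""
    ev_t = EditEvent("templated_insert_fusion", (cuts["g4"], cuts["g6"]),
                     insert_source=("g2", 837, 80))
    arch = apply_event(AlleleArchitecture.identity(array), ev_t, array)
    ev, _ = _evidence(array, sim_config, ref, arch)
    sigs = {j.signature() for j in ev.junctions}
    assert ("P", "g6", "g4") in sigs
    (j,) = [j for j in ev.junctions if j.signature() == ("P", "g6", "g4")]
    # microhomology at the insert edges can shift the reported copy by a
    # base or two; the net length change is exact
    assert j.net_indel == 80
    assert abs(len(j.inserted) - 80) <= 2
    assert j.insert_source is not None
    src_locus, src_t, src_len = j.insert_source
    assert src_locus == "g2" and abs(src_t - 837) <= 2
    assert j.inserted in array.gene_sequence("g2")[830:925]


def test_upstream_joint_detected_by_capture(array, sim_config, ref):
    """A fusion whose joint sits upstream of the amplicon forward primer is
    invisible to amplicon reads but visible here."""
    g1, g7 = array.gene("g1"), array.gene("g7")
    ev_d = EditEvent("dropout_fusion",
                     (g1.t_to_axis(797), g7.t_to_axis(797)))
    arch = apply_event(AlleleArchitecture.identity(array), ev_d, array)
    ev, _ = _evidence(array, sim_config, ref, arch)
    sigs = {j.signature() for j in ev.junctions}
    assert ("P", "g7", "g1") in sigs
    (j,) = [j for j in ev.junctions if j.signature() == ("P", "g7", "g1")]
    assert j.net_indel == 0


def test_read_level_segmentation_of_known_joint(array, ref, cuts):
    """A single read straddling a joint with enough flank on both sides
    resolves the junction without assembly."""
    arch = apply_event(AlleleArchitecture.identity(array),
                       EditEvent("dropout_fusion", (cuts["g1"], cuts["g5"])),
                       array)
    rendered = render_sequence(arch, array)
    joint = cuts["g1"]  # rendered coordinate of the joint
    read = rendered[joint - 75:joint + 75]
    j = segment_junction(read, ref, array, provenance="read_pair")
    assert j is not None
    assert j.signature() == ("P", "g5", "g1")
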