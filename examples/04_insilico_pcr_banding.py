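"""In-silico PCR: multigene banding patterns and NA-allele predictions.

Primer binding allows up to 2 mismatches but requires an exact 3'-terminal
base — doubly mismatched sites still amplify (weak, nonspecific products)
while one 3' mispair kills the site.
"""

from tagedit.model import AlleleArchitecture, EditEvent, apply_event, gene_states, junction_set
from tagedit.pcr import predict_banding
from tagedit.simulate import (
    LineRecord, SimulationConfig, TruthRecord, amplicon_primer_pair,
    build_array, line_genome, long_primer_pair)

config = SimulationConfig()
array = build_array(config, seed=1)
panel = [long_primer_pair(array), amplicon_primer_pair(array)]


def banding(label, arch):
    truth = TruthRecord(label, gene_states(arch, array), [],
                        junction_set(arch, array), {})
    genome = line_genome(LineRecord(label, arch, truth), array)
    rep = predict_banding(label, genome, arch, array, panel)
    print(f"{label}:")
    for pid, bands in rep.bands.items():
        pretty = ", ".join(f"{l} bp x{m}" for l, m in bands)
        print(f"  {pid:10s} {pretty}")
    print(f"  NA predicted: {rep.na_genes or 'none'}   "
          f"control band: {rep.control_ok}")


banding("WT", AlleleArchitecture.identity(array))

cuts = {g.id: g.cut_point for g in array.array_genes()}
arch = apply_event(AlleleArchitecture.identity(array),
                   EditEvent("dropout_fusion", (cuts["g3"], cuts["g7"])),
                   array)
banding("dropout g4-g6 (5'-g7/3'-g3 fusion)", arch)

# The WT multigene reaction gives the full ~2 kb band cluster (one product
# per paralog) plus the shorter nontarget pseudogene band that serves as a
# loading control; the dropout line loses four copies from the cluster and
# its four lost genes are predicted NA.
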