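"""Shared vocabulary: gene classes, TF DNA-binding-domain classes, the seven
fast-acting neurotransmitter pathway genes, and the lineage-tracing
transgenes."""

GENE_CLASSES = (
    "tf",
    "neuropeptide",
    "nt_pathway",
    "transgene",
    "mito",
    "glial_marker",
    "sex_marker",
    "other",
)

# Six DNA-binding-domain classes used for combinatorial-code analysis.
TF_CLASSES = (
    "zinc_finger",
    "helix_turn_helix",
    "homeodomain",
    "basic_domain",
    "unspecified_dbd",
    "hmg",
)

# Fast-acting neurotransmitter pathway genes and the neuron class each marks.
NT_CLASS_OF_GENE = {
    "VGlut": "glutamatergic",
    "VAChT": "cholinergic",
    "Gad1": "GABAergic",
    "Tdc2": "tyraminergic",
    "ple": "dopaminergic",
    "SerT": "serotonergic",
    "Tbh": "octopaminergic",
}
NT_GENES = tuple(NT_CLASS_OF_GENE)

# Recombinase-activated reporters marking T2-neuroblast-derived cells.
TRANSGENES = ("FLP", "GFP", "RFP")

GLIAL_MARKER = "repo"

MITO_GENES = ("mt:CoI", "mt:CoII", "mt:CoIII", "mt:ND1", "mt:Cyt-b")
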