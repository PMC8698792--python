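"""EmbedDTI: drug-target binding-affinity prediction.

Drugs are represented by two molecular graphs (atoms, and segmented
substructures), each processed by an attention-augmented graph
convolutional network; proteins by pretrained amino-acid embeddings fed to
a 1-D CNN. The three 128-d branch vectors are fused for affinity
regression on the pKd or KIBA scale.
"""

from importlib import resources

from .chem_graphs import (
    ATOM_FEATURE_DIM,
    SUBSTRUCTURE_FEATURE_DIM,
    AtomGraph,
    Molecule,
    SmilesParseError,
    Substructure,
    SubstructureGraph,
    SubstructureVocabulary,
    atom_feature_vector,
    build_atom_graph,
    build_substructure_graph,
    build_vocabulary,
    find_simple_rings,
    parse_smiles,
    segment_substructures,
    substructure_feature_vector,
)
from .data_pipeline import (
    AffinityRecord,
    DatasetSplit,
    generate_synthetic_dataset,
    kd_to_pkd,
    load_matrix_style,
    load_triples_csv,
    save_triples_csv,
    split_dataset,
    toy_affinity,
)
from .metrics import concordance_index, mse, pearson, spearman, step_h
from .neural_model import (
    ModelConfig,
    ModelParams,
    TrainState,
    attention_scores,
    featurize_record,
    fuse_and_predict,
    gcn_layer_forward,
    graph_branch_forward,
    init_model_params,
    load_checkpoint,
    node_attention,
    normalize_adjacency,
    predict,
    protein_branch_forward,
    save_checkpoint,
    train_model,
)
from .protein_embedding import (
    AminoAcidVocabulary,
    CooccurrenceMatrix,
    EmbeddingMatrix,
    EncodedProtein,
    build_cooccurrence,
    encode_protein,
    train_glove,
)
from .screening import ScreeningResult, screen_rank

__version__ = "0.1.0"


def screening_candidate_smiles() -> list[str]:
    """The ten published K-Ras virtual-screening candidate SMILES."""
    text = (resources.files("embeddti") / "data" / "kras_screen_candidates.smi").read_text()
    return [line for line in text.splitlines() if line.strip()]
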