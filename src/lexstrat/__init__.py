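"""lexstrat: language-based population stratification for genomic sampling.

Builds normalized Levenshtein distance (LDN) matrices from gloss-aligned
multilingual wordlists, recovers population structure (classical MDS,
hierarchical clustering, neighbor joining), compares lexical, genetic
(F_ST) and geographic distance matrices with Mantel permutation tests, and
prioritizes representative populations for genomic sequencing panels.
"""

from importlib import resources
from pathlib import Path

from .compare import GeoTable, MantelResult, geo_matrix, mantel, mantel_ci
from .lexdist import LdnParams, ldn, levenshtein, pairwise_ldn
from .prioritize import (
    BridgeScore,
    Panel,
    bridge_scores,
    select_maximin,
    select_medoids,
)
from .structure import (
    Embedding,
    Tree,
    TreeNode,
    agglomerative,
    classical_mds,
    cophenetic_matrix,
    cut_tree,
    neighbor_joining,
    to_newick,
    tree_distance_matrix,
)
from .synthlex import SimConfig, simulate_coupled_fst, simulate_wordlist
from .wordlist_io import (
    MISSING,
    DistanceMatrix,
    ValidationError,
    WordList,
    read_matrix,
    read_wordlist,
    write_matrix,
)

__version__ = "0.1.0"


def fixture_path(name: str) -> Path:
    """Path of a packaged data fixture (e.g. ``table2_fst.csv``).

    The ``table2_*`` fixtures carry the published Kenyan pairwise F_ST and
    LDN values exactly as printed (rounded); they are not recomputations
    from the underlying wordlist.
    """
    return Path(resources.files("lexstrat").joinpath("data", name))


__all__ = [
    "MISSING",
    "WordList",
    "DistanceMatrix",
    "ValidationError",
    "read_wordlist",
    "read_matrix",
    "write_matrix",
    "LdnParams",
    "levenshtein",
    "ldn",
    "pairwise_ldn",
    "Embedding",
    "Tree",
    "TreeNode",
    "classical_mds",
    "agglomerative",
    "cut_tree",
    "cophenetic_matrix",
    "neighbor_joining",
    "to_newick",
    "tree_distance_matrix",
    "MantelResult",
    "GeoTable",
    "mantel",
    "mantel_ci",
    "geo_matrix",
    "Panel",
    "BridgeScore",
    "select_maximin",
    "select_medoids",
    "bridge_scores",
    "SimConfig",
    "simulate_wordlist",
    "simulate_coupled_fst",
    "fixture_path",
]
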