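"""Synthetic wordlists with known family structure.

Emulates the three-family (Bantu / Nilotic / Cushitic-like) setting: per
gloss a random root word evolves along a balanced two-level tree — a long
branch from the root to each family ancestor, short branches from each
ancestor to its member varieties — by an i.i.d. per-character edit process
(substitution-dominated, with occasional insertions and deletions) whose
intensity is rate x branch length. Since the between-family branches are
much longer than the within-family ones, family membership is recoverable
from the resulting LDN matrix, with the divergence contrast fully under
the caller's control.

An optional hybrid variety draws each gloss from one of two donor
families, emulating a contact/borrowing "bridge population". A coupled
pseudo-F_ST matrix can be derived from the generating tree's path lengths
for testing matrix-comparison machinery; it is a rescaled tree metric plus
noise, not a coalescent quantity.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, replace

import numpy as np

from .structure import Tree, TreeNode, tree_distance_matrix
from .wordlist_io import DistanceMatrix, WordList

__all__ = ["SimConfig", "simulate_wordlist", "simulate_coupled_fst"]

ALPHABET = string.ascii_lowercase

#: Conditional on an edit event at a character: substitution / deletion /
#: insertion-after shares. Substitution-dominated, as in real orthographic
#: divergence between related word forms.
EDIT_KIND_PROBS = {"sub": 0.8, "del": 0.1, "ins": 0.1}


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration.

    Defaults are the reference condition used throughout the test suite:
    3 families x 4 varieties, 60 glosses, root words of 6 letters, edit
    probability 0.12 per character per unit branch length, within-family
    depth 0.3 versus between-family depth 3.0, and 5% missing cells.
    """

    n_families: int = 3
    varieties_per_family: int = 4
    n_glosses: int = 60
    root_word_length: int = 6
    edit_prob: float = 0.12
    within_family_depth: float = 0.3
    between_family_depth: float = 3.0
    missing_rate: float = 0.05
    hybrid_spec: tuple[str, tuple[str, str], float] | None = None
    genetic_coupling: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("edit_prob", "missing_rate", "genetic_coupling"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.root_word_length < 1:
            raise ValueError("root_word_length must be >= 1 (empty words)")
        if self.between_family_depth <= self.within_family_depth:
            raise ValueError("between_family_depth must exceed within_family_depth")
        if self.hybrid_spec is not None:
            _, donors, mix = self.hybrid_spec
            if len(donors) != 2:
                raise ValueError("hybrid_spec needs exactly two donor families")
            if not 0 <= mix <= 1:
                raise ValueError("mixing proportion outside [0, 1]")


def _evolve(word: str, branch_length: float, rate: float, rng: np.random.Generator) -> str:
    """Apply the per-character edit process along one branch."""
    p_event = min(1.0, rate * branch_length)
    chars = list(word)
    out: list[str] = []
    for ch in chars:
        if rng.random() >= p_event:
            out.append(ch)
            continue
        u = rng.random()
        if u < EDIT_KIND_PROBS["sub"]:
            out.append(ALPHABET[rng.integers(len(ALPHABET))])
        elif u < EDIT_KIND_PROBS["sub"] + EDIT_KIND_PROBS["del"]:
            continue  # deletion
        else:
            out.append(ch)
            out.append(ALPHABET[rng.integers(len(ALPHABET))])
    if not out:  # never let a word vanish entirely
        out.append(ALPHABET[rng.integers(len(ALPHABET))])
    return "".join(out)


def _random_word(length: int, rng: np.random.Generator) -> str:
    return "".join(ALPHABET[i] for i in rng.integers(len(ALPHABET), size=length))


def family_names(n: int) -> list[str]:
    return [f"fam{i + 1}" for i in range(n)]


def simulate_wordlist(c: SimConfig) -> tuple[WordList, Tree, dict[str, str]]:
    """Generate a wordlist, its generating tree, and the true partition.

    Returns ``(wordlist, true_tree, true_partition)`` where the partition
    maps each variety to its family label (a hybrid is assigned to its
    first donor family). Fully deterministic given ``c.seed``.
    """
    rng = np.random.default_rng(c.seed)
    fams = family_names(c.n_families)
    varieties = [
        f"{fam}_v{v + 1}" for fam in fams for v in range(c.varieties_per_family)
    ]
    partition = {name: name.split("_")[0] for name in varieties}

    glosses = [f"g{i + 1:03d}" for i in range(c.n_glosses)]
    forms: dict[tuple[str, str], str | None] = {}
    donor_forms: dict[tuple[str, str], str] = {}  # first variety per family
    for g in glosses:
        root = _random_word(c.root_word_length, rng)
        for fam in fams:
            ancestor = _evolve(root, c.between_family_depth, c.edit_prob, rng)
            for v in range(c.varieties_per_family):
                name = f"{fam}_v{v + 1}"
                form = _evolve(ancestor, c.within_family_depth, c.edit_prob, rng)
                forms[(name, g)] = form
                if v == 0:
                    donor_forms[(fam, g)] = form

    if c.hybrid_spec is not None:
        hybrid_name, (fam_a, fam_b), mix = c.hybrid_spec
        for fam in (fam_a, fam_b):
            if fam not in fams:
                raise ValueError(f"unknown donor family {fam!r}")
        varieties.append(hybrid_name)
        partition[hybrid_name] = fam_a
        for g in glosses:
            donor = fam_a if rng.random() < mix else fam_b
            forms[(hybrid_name, g)] = donor_forms[(donor, g)]

    if c.missing_rate > 0:
        for key in list(forms):
            if rng.random() < c.missing_rate:
                del forms[key]

    family_map = dict(partition)
    wordlist = WordList(varieties, glosses, forms, family=family_map)

    root_node = TreeNode()
    tree_leaves: list[str] = []
    for fam in fams:
        fam_node = TreeNode(name=None, length=c.between_family_depth)
        for v in range(c.varieties_per_family):
            leaf = f"{fam}_v{v + 1}"
            fam_node.children.append(TreeNode(name=leaf, length=c.within_family_depth))
            tree_leaves.append(leaf)
        root_node.children.append(fam_node)
    tree = Tree(root=root_node, rooted=True, labels=tree_leaves)
    return wordlist, tree, partition


def simulate_coupled_fst(
    true_tree: Tree, coupling: float, noise_seed: int = 0
) -> DistanceMatrix:
    """Pseudo-F_ST matrix coupled to the generating tree.

    Tree path lengths are rescaled to [0, 0.2] (a realistic F_ST range for
    strongly differentiated human populations) and mixed with independent
    uniform noise on the same scale:
    ``F = coupling * scaled_path + (1 - coupling) * noise``.
    """
    if not 0 <= coupling <= 1:
        raise ValueError("coupling outside [0, 1]")
    paths = tree_distance_matrix(true_tree)
    n = len(paths)
    scaled = 0.2 * paths.values / paths.values.max()
    rng = np.random.default_rng(noise_seed)
    noise = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    noise[iu] = rng.uniform(0.0, 0.2, size=len(iu[0]))
    noise = noise + noise.T
    values = coupling * scaled + (1 - coupling) * noise
    values = (values + values.T) / 2
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(list(paths.labels), values, kind="genetic")


def reference_config(seed: int = 0, **overrides) -> SimConfig:
    """The reference simulation condition with a caller-chosen seed."""
    return replace(SimConfig(), seed=seed, **overrides)
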