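"""Three-level hierarchical molecular graphs.

A molecule becomes a graph with three node levels:

* **atom** nodes carry a 31-d one-hot feature vector
  (type 11 | degree 6 | formal charge 5 | chiral tag 4 | hybridization 4 |
  aromatic 1);
* **motif** nodes are the BRICS fragments of the molecule (all-ones initial
  feature so one shared linear projection serves every level);
* a single **super** node (zero initial feature) connected to every motif;
  its embedding after message passing is the molecule-level representation.

Edges: chemical bonds (atom–atom, 6-d one-hot: bond type 4 | in-ring 1 |
conjugated 1), and virtual hierarchical edges motif↔member-atom and
super↔motif whose raw feature is all-zero; after projection virtual edges
receive a dedicated learned 64-d embedding. Hydrogens are implicit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import BRICS

ATOM_DIM = 31
BOND_DIM = 6

_ATOM_TYPES = ["C", "N", "O", "F", "P", "S", "Cl", "Br", "I", "B"]  # + other
_CHIRAL_TAGS = [
    Chem.ChiralType.CHI_UNSPECIFIED,
    Chem.ChiralType.CHI_TETRAHEDRAL_CW,
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
]  # + other
_HYBRIDIZATIONS = [
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
]  # + other
_BOND_TYPES = [
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
]

# block layout of the 31-d atom vector: (offset, length)
ATOM_BLOCKS = {
    "type": (0, 11),
    "degree": (11, 6),
    "formal_charge": (17, 5),
    "chiral_tag": (22, 4),
    "hybridization": (26, 4),
    "aromatic": (30, 1),
}


def _onehot(index: int, length: int) -> np.ndarray:
    v = np.zeros(length)
    v[index] = 1.0
    return v


def featurize_atom(atom: Chem.Atom) -> np.ndarray:
    """31-d one-hot atom feature. Categories outside the fixed vocabularies
    map to the final "other" slot of their block."""
    sym = atom.GetSymbol()
    t = _ATOM_TYPES.index(sym) if sym in _ATOM_TYPES else 10
    deg = min(atom.GetDegree(), 5)
    charge = int(np.clip(atom.GetFormalCharge(), -2, 2)) + 2
    tag = atom.GetChiralTag()
    chiral = _CHIRAL_TAGS.index(tag) if tag in _CHIRAL_TAGS else 3
    hyb = atom.GetHybridization()
    hybrid = _HYBRIDIZATIONS.index(hyb) if hyb in _HYBRIDIZATIONS else 3
    return np.concatenate(
        [
            _onehot(t, 11),
            _onehot(deg, 6),
            _onehot(charge, 5),
            _onehot(chiral, 4),
            _onehot(hybrid, 4),
            [float(atom.GetIsAromatic())],
        ]
    )


def featurize_bond(bond: Chem.Bond) -> np.ndarray:
    """6-d one-hot bond feature: type | in-ring | conjugated."""
    bt = bond.GetBondType()
    t = _BOND_TYPES.index(bt) if bt in _BOND_TYPES else 0
    return np.concatenate(
        [_onehot(t, 4), [float(bond.IsInRing())], [float(bond.GetIsConjugated())]]
    )


def brics_motifs(mol: Chem.Mol) -> list[set[int]]:
    """Partition heavy atoms into BRICS fragments.

    All BRICS-cleavable bonds are cut simultaneously; the connected
    components of the remaining bond graph are the motifs, ordered by their
    smallest member atom index. A molecule without cleavable bonds is one
    motif.
    """
    n = mol.GetNumAtoms()
    cut = {tuple(sorted(b[0])) for b in BRICS.FindBRICSBonds(mol)}
    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if tuple(sorted((i, j))) in cut:
            continue
        adj[i].append(j)
        adj[j].append(i)
    seen: set[int] = set()
    motifs: list[set[int]] = []
    for start in range(n):
        if start in seen:
            continue
        comp, stack = set(), [start]
        while stack:
            a = stack.pop()
            if a in comp:
                continue
            comp.add(a)
            stack.extend(b for b in adj[a] if b not in comp)
        seen |= comp
        motifs.append(comp)
    motifs.sort(key=min)
    return motifs


@dataclass
class HierMolGraph:
    """The assembled hierarchical graph.

    Node order: atoms ``0..n_atoms-1``, motifs ``n_atoms..n_atoms+n_motifs-1``,
    super node last. ``edge_raw`` is all-zero at virtual edges and non-edges;
    ``virtual_mask`` marks the hierarchical (motif–atom, super–motif) edges.
    """

    smiles: str
    n_atoms: int
    n_motifs: int
    node_raw: np.ndarray  # (N, 31)
    edge_raw: np.ndarray  # (N, N, 6)
    adj: np.ndarray  # (N, N) bool
    virtual_mask: np.ndarray  # (N, N) bool
    level_of: list[str]
    motif_members: list[set[int]]
    node_latent: np.ndarray | None = None
    edge_latent: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return self.n_atoms + self.n_motifs + 1

    @property
    def super_index(self) -> int:
        return self.n_nodes - 1

    def to_json(self) -> str:
        edges = [
            [int(i), int(j), self.edge_raw[i, j].tolist()]
            for i in range(self.n_nodes)
            for j in range(self.n_nodes)
            if self.adj[i, j]
        ]
        return json.dumps(
            {
                "smiles": self.smiles,
                "levels": self.level_of,
                "node_raw": self.node_raw.tolist(),
                "edges": edges,
                "motif_members": [sorted(m) for m in self.motif_members],
            }
        )


def build_hier_graph(mol_or_smiles) -> HierMolGraph:
    """Build the three-level graph for a molecule (SMILES or RDKit Mol)."""
    if isinstance(mol_or_smiles, str):
        mol = Chem.MolFromSmiles(mol_or_smiles)
        if mol is None:
            raise ValueError(f"invalid SMILES: {mol_or_smiles!r}")
        smiles = mol_or_smiles
    else:
        mol = mol_or_smiles
        smiles = Chem.MolToSmiles(mol)
    n_atoms = mol.GetNumAtoms()
    motifs = brics_motifs(mol)
    n_motifs = len(motifs)
    n = n_atoms + n_motifs + 1
    node_raw = np.zeros((n, ATOM_DIM))
    for atom in mol.GetAtoms():
        node_raw[atom.GetIdx()] = featurize_atom(atom)
    node_raw[n_atoms : n_atoms + n_motifs] = 1.0  # motif rows: all-ones
    # super row stays all-zeros

    edge_raw = np.zeros((n, n, BOND_DIM))
    adj = np.zeros((n, n), dtype=bool)
    virtual = np.zeros((n, n), dtype=bool)
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        f = featurize_bond(bond)
        edge_raw[i, j] = f
        edge_raw[j, i] = f
        adj[i, j] = adj[j, i] = True
    for k, members in enumerate(motifs):
        m = n_atoms + k
        for a in members:
            adj[m, a] = adj[a, m] = True
            virtual[m, a] = virtual[a, m] = True
        adj[n - 1, m] = adj[m, n - 1] = True
        virtual[n - 1, m] = virtual[m, n - 1] = True

    levels = ["atom"] * n_atoms + ["motif"] * n_motifs + ["super"]
    return HierMolGraph(smiles, n_atoms, n_motifs, node_raw, edge_raw, adj, virtual, levels, motifs)


def project_features(node_raw, edge_raw, virtual_mask, node_W, node_b, edge_W, edge_b, virtual_embed):
    """Shared projection math for raw features → latent features.

    Works identically on NumPy arrays and autodiff Tensors (the caller
    supplies matching types). Virtual edges get the learned ``virtual_embed``
    added on top of the projected all-zero raw feature; non-edges keep the
    zero-input image of the edge map.
    """
    node_latent = node_raw @ node_W + node_b
    edge_latent = edge_raw @ edge_W + edge_b
    vm = virtual_mask
    if isinstance(vm, np.ndarray):
        vm = vm.astype(float)
    if vm.ndim == 2:
        n = vm.shape[0]
        vm = vm.reshape((n, n, 1))
    edge_latent = edge_latent + vm * virtual_embed
    return node_latent, edge_latent


def project_latents(
    g: HierMolGraph,
    node_W: np.ndarray,
    node_b: np.ndarray,
    edge_W: np.ndarray,
    edge_b: np.ndarray,
    virtual_embed: np.ndarray | None = None,
) -> HierMolGraph:
    """Fill ``g.node_latent`` (N×256) and ``g.edge_latent`` (N×N×64)."""
    if node_W.shape[0] != ATOM_DIM or edge_W.shape[0] != BOND_DIM:
        raise ValueError("projection maps must take 31-d node / 6-d edge inputs")
    if virtual_embed is None:
        virtual_embed = np.zeros(edge_W.shape[1])
    g.node_latent, g.edge_latent = project_features(
        g.node_raw, g.edge_raw, g.virtual_mask, node_W, node_b, edge_W, edge_b, virtual_embed
    )
    return g
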