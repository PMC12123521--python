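"""Dataset I/O, canonicalization, depiction rendering and scaffold splitting.

Molecule datasets follow the MoleculeNet CSV dialect: one row per molecule,
a SMILES column and one or more binary label columns where an empty cell
means "label unknown for this task". Missing labels are carried as NaN and
masked downstream — they are never imputed.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.Draw import rdMolDraw2D
from rdkit.Chem.Scaffolds import MurckoScaffold

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

MISSING = float("nan")


@dataclass
class MoleculeRecord:
    """One molecule with per-task binary labels.

    ``labels[k]`` is 0.0, 1.0 or NaN (missing) and aligns with
    ``task_names[k]``.
    """

    smiles: str
    labels: np.ndarray
    task_names: list[str]
    source: str = ""

    def label_for(self, task: str) -> float:
        try:
            return float(self.labels[self.task_names.index(task)])
        except ValueError:
            return MISSING


@dataclass
class DepictionImage:
    """A 3x224x224 RGB raster of a 2-D molecular drawing, values in [0,1]."""

    pixels: np.ndarray
    smiles: str


@dataclass
class SplitAssignment:
    train_idx: list[int]
    valid_idx: list[int]
    test_idx: list[int]
    scaffold_of: dict[int, str] = field(default_factory=dict)


def canonical_smiles(smiles: str) -> str | None:
    """Canonical SMILES, or None if the string does not parse to a molecule
    with at least one heavy atom."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumHeavyAtoms() == 0:
        return None
    return Chem.MolToSmiles(mol)


def read_dataset(
    path,
    smiles_column: str = "smiles",
    label_columns: list[str] | None = None,
    source: str = "",
    stats: dict | None = None,
) -> list[MoleculeRecord]:
    """Read a MoleculeNet-dialect CSV into records.

    Unparseable SMILES rows are skipped (count reported in ``stats`` under
    ``"n_skipped"`` and logged). Empty label cells become NaN (missing).
    Raises ``FileNotFoundError`` for a missing file and ``ValueError`` if no
    row survives.
    """
    df = pd.read_csv(path)
    if smiles_column not in df.columns:
        raise ValueError(f"column {smiles_column!r} not found in {path}")
    if label_columns is None:
        label_columns = [c for c in df.columns if c != smiles_column]
    for c in label_columns:
        if c not in df.columns:
            raise ValueError(f"label column {c!r} not found in {path}")

    records: list[MoleculeRecord] = []
    n_skipped = 0
    for _, row in df.iterrows():
        can = canonical_smiles(str(row[smiles_column]))
        if can is None:
            n_skipped += 1
            continue
        labels = np.array(
            [MISSING if pd.isna(row[c]) else float(row[c]) for c in label_columns]
        )
        records.append(MoleculeRecord(can, labels, list(label_columns), source or str(path)))
    if n_skipped:
        logger.warning("skipped %d unparseable SMILES rows in %s", n_skipped, path)
    if stats is not None:
        stats["n_skipped"] = n_skipped
    if not records:
        raise ValueError(f"no parseable molecules in {path}")
    return records


def write_dataset(records: list[MoleculeRecord], path, smiles_column: str = "smiles") -> None:
    """Write records back to the CSV dialect (missing labels as empty cells)."""
    tasks: list[str] = []
    for r in records:
        for t in r.task_names:
            if t not in tasks:
                tasks.append(t)
    rows = []
    for r in records:
        row = {smiles_column: r.smiles}
        for t in tasks:
            v = r.label_for(t)
            row[t] = "" if math.isnan(v) else int(v)
        rows.append(row)
    pd.DataFrame(rows, columns=[smiles_column] + tasks).to_csv(path, index=False)


def merge_multitask(
    datasets: list[list[MoleculeRecord]], stats: dict | None = None
) -> list[MoleculeRecord]:
    """Merge record lists into one multitask pool keyed by canonical SMILES.

    Duplicates collapse into a single record carrying the union of task
    labels; a conflicting duplicate label for the same task keeps the
    first-seen value (conflict counted and logged).
    """
    task_names: list[str] = []
    for ds in datasets:
        for r in ds:
            for t in r.task_names:
                if t not in task_names:
                    task_names.append(t)
    merged: dict[str, np.ndarray] = {}
    order: list[str] = []
    n_conflicts = 0
    for ds in datasets:
        for r in ds:
            if r.smiles not in merged:
                merged[r.smiles] = np.full(len(task_names), MISSING)
                order.append(r.smiles)
            row = merged[r.smiles]
            for t, v in zip(r.task_names, r.labels):
                if math.isnan(v):
                    continue
                k = task_names.index(t)
                if math.isnan(row[k]):
                    row[k] = v
                elif row[k] != v:
                    n_conflicts += 1
                    logger.warning("label conflict for %s on task %s; keeping first", r.smiles, t)
    if stats is not None:
        stats["n_conflicts"] = n_conflicts
    return [MoleculeRecord(s, merged[s], list(task_names), "merged") for s in order]


def render_depiction(smiles: str, size: int = 224) -> DepictionImage:
    """Render a deterministic 2-D depiction (white background, fixed
    coordinate generation, no atom indices) as a 3xSIZExSIZE array in [0,1].

    Raises ``ValueError`` for an invalid SMILES.
    """
    from PIL import Image

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    Chem.rdDepictor.SetPreferCoordGen(True)
    Chem.rdDepictor.Compute2DCoords(mol)
    drawer = rdMolDraw2D.MolDraw2DCairo(size, size)
    opts = drawer.drawOptions()
    opts.addAtomIndices = False
    opts.fixedBondLength = -1
    drawer.DrawMolecule(mol)
    drawer.FinishDrawing()
    png = drawer.GetDrawingText()
    img = Image.open(io.BytesIO(png)).convert("RGB")
    arr = np.asarray(img, dtype=np.float32) / 255.0  # (H, W, 3)
    return DepictionImage(arr.transpose(2, 0, 1).copy(), smiles)


def save_depiction_png(img: DepictionImage, path) -> None:
    from PIL import Image

    arr = (img.pixels.transpose(1, 2, 0) * 255.0).round().astype(np.uint8)
    Image.fromarray(arr).save(path)


def murcko_scaffold(smiles: str) -> str:
    """Bemis–Murcko framework SMILES; acyclic molecules (empty framework)
    fall back to their own canonical SMILES so each forms its own group."""
    scaf = MurckoScaffold.MurckoScaffoldSmiles(smiles=smiles, includeChirality=False)
    return scaf if scaf else canonical_smiles(smiles)


def scaffold_split(
    records: list[MoleculeRecord],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitAssignment:
    """Deterministic scaffold split.

    Scaffold groups are ordered by descending size with lexicographic
    tie-break, then greedily fill train up to round(f_train*n), then valid up
    to round(f_valid*n); the remainder goes to test. Common scaffolds land in
    train. The ordering is fully deterministic, so ``seed`` does not alter
    the assignment; it is accepted for interface stability.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    n = len(records)
    if n < 10:
        raise ValueError("need at least 10 molecules to split")
    groups: dict[str, list[int]] = {}
    scaffold_of: dict[int, str] = {}
    for i, r in enumerate(records):
        s = murcko_scaffold(r.smiles)
        scaffold_of[i] = s
        groups.setdefault(s, []).append(i)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    cut_train = round(fractions[0] * n)
    cut_valid = round(fractions[1] * n)
    train, valid, test = [], [], []
    for _, idxs in ordered:
        if len(train) + len(idxs) <= cut_train:
            train.extend(idxs)
        elif len(valid) + len(idxs) <= cut_valid:
            valid.extend(idxs)
        else:
            test.extend(idxs)
    return SplitAssignment(train, valid, test, scaffold_of)


def save_split_csvs(records, split: SplitAssignment, prefix) -> None:
    for name, idxs in (("train", split.train_idx), ("valid", split.valid_idx), ("test", split.test_idx)):
        write_dataset([records[i] for i in idxs], f"{prefix}_{name}.csv")
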