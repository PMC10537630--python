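"""Molecular featurization: descriptors, fingerprints, chemotype bits.

Four feature families are produced, all as a common
:class:`FeatureMatrix` container:

- the full RDKit 1D/2D descriptor battery (~210 real-valued columns),
- hashed fingerprints (MACCS keys, Daylight-style path fingerprints,
  circular ECFP/FCFP at radius 1-3),
- chemotype fingerprints: one bit per named SMARTS substructure,
- a genetic-algorithm descriptor subset selector driven by inner-CV AUC.

Descriptor prefiltering removes constant, low-variance and highly
intercorrelated columns before subset selection.
"""

from __future__ import annotations

import importlib.resources
import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, MACCSkeys, rdFingerprintGenerator
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .curation import MoleculeRecord

logger = logging.getLogger(__name__)

FINGERPRINT_KINDS = ("maccs", "path_fp", "ecfp", "fcfp")

#: Full RDKit descriptor battery, in its canonical order.
DESCRIPTOR_NAMES: tuple[str, ...] = tuple(name for name, _ in Descriptors.descList)


@dataclass
class FeatureMatrix:
    """Compounds x features block with names and provenance.

    ``binary=True`` promises entries in {0,1}. ``meta`` records how the
    block was produced (kind parameters, excluded compounds, ...).
    """

    values: np.ndarray
    feature_names: list[str]
    kind: str
    binary: bool
    compound_ids: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        n, p = self.values.shape
        if n != len(self.compound_ids):
            raise ValueError("row count must equal compound count")
        if p != len(self.feature_names):
            raise ValueError("column count must equal feature-name count")
        if np.isnan(self.values).any():
            raise ValueError("FeatureMatrix must not contain missing values")
        if self.binary and not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("binary matrix must contain only 0/1 entries")

    @property
    def n_compounds(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select(self, names: Sequence[str]) -> "FeatureMatrix":
        """Column subset, preserving the order given in ``names``."""
        idx = [self.feature_names.index(n) for n in names]
        return FeatureMatrix(
            values=self.values[:, idx],
            feature_names=list(names),
            kind=self.kind,
            binary=self.binary,
            compound_ids=list(self.compound_ids),
            meta={**self.meta, "selected_from": self.n_features},
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "compound_id", self.compound_ids)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, kind: str, binary: bool) -> "FeatureMatrix":
        df = pd.read_csv(path)
        ids = df.pop("compound_id").astype(str).tolist()
        return cls(
            values=df.to_numpy(dtype=float),
            feature_names=list(df.columns),
            kind=kind,
            binary=binary,
            compound_ids=ids,
        )


def _as_mol(record: MoleculeRecord | Chem.Mol | str) -> Chem.Mol:
    if isinstance(record, Chem.Mol):
        return record
    smiles = record if isinstance(record, str) else (
        record.canonical_smiles or record.smiles
    )
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"cannot parse SMILES {smiles!r}")
    return mol


def _record_id(record: MoleculeRecord | Chem.Mol | str, i: int) -> str:
    if isinstance(record, MoleculeRecord):
        return record.record_id
    return f"mol{i}"


# ---------------------------------------------------------------------------
# Descriptors


def compute_descriptors(
    records: Sequence[MoleculeRecord | Chem.Mol | str],
) -> FeatureMatrix:
    """Compute the full RDKit 1D/2D descriptor battery, one row per compound.

    Molecules for which any descriptor fails (non-finite result) are
    excluded from the matrix and listed in ``meta['failed_compounds']``.
    """
    rows: list[np.ndarray] = []
    ids: list[str] = []
    failed: list[str] = []
    for i, rec in enumerate(records):
        rid = _record_id(rec, i)
        mol = _as_mol(rec)
        vals = Descriptors.CalcMolDescriptors(mol)
        arr = np.array([vals[name] for name in DESCRIPTOR_NAMES], dtype=float)
        if not np.isfinite(arr).all():
            failed.append(rid)
            logger.warning("descriptor failure for %s; row excluded", rid)
            continue
        rows.append(arr)
        ids.append(rid)
    values = (
        np.vstack(rows) if rows else np.empty((0, len(DESCRIPTOR_NAMES)))
    )
    return FeatureMatrix(
        values=values,
        feature_names=list(DESCRIPTOR_NAMES),
        kind="descriptor",
        binary=False,
        compound_ids=ids,
        meta={"failed_compounds": failed},
    )


@dataclass(frozen=True)
class PrefilterConfig:
    """Descriptor prefilter thresholds.

    ``r2_max``: squared Pearson correlation above which one member of a
    descriptor pair is dropped. ``std_min``: minimum column standard
    deviation (population, ddof=0).
    """

    r2_max: float = 0.9
    std_min: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.r2_max <= 1:
            raise ValueError("r2_max must be in (0, 1]")
        if self.std_min < 0:
            raise ValueError("std_min must be >= 0")


def prefilter_descriptors(
    m: FeatureMatrix, cfg: PrefilterConfig | None = None
) -> FeatureMatrix:
    """Drop constant, low-variance and intercorrelated descriptor columns.

    Of each pair with squared correlation above ``cfg.r2_max`` the later
    column (larger original index) is dropped; survivors keep their
    original order.
    """
    cfg = cfg or PrefilterConfig()
    if m.kind != "descriptor":
        raise ValueError("prefilter applies to descriptor matrices")
    if m.n_compounds < 3:
        raise ValueError("need at least 3 compounds for correlation prefiltering")

    stds = m.values.std(axis=0)
    keep = [j for j in range(m.n_features) if stds[j] > 0 and stds[j] >= cfg.std_min]

    # Greedy scan in original order: drop the later member of any
    # too-correlated pair whose earlier member survived.
    surviving: list[int] = []
    for j in keep:
        ok = True
        for i in surviving:
            r = np.corrcoef(m.values[:, i], m.values[:, j])[0, 1]
            if r * r > cfg.r2_max:
                ok = False
                break
        if ok:
            surviving.append(j)

    return FeatureMatrix(
        values=m.values[:, surviving],
        feature_names=[m.feature_names[j] for j in surviving],
        kind="descriptor",
        binary=False,
        compound_ids=list(m.compound_ids),
        meta={**m.meta, "prefilter": {"r2_max": cfg.r2_max, "std_min": cfg.std_min,
                                      "n_before": m.n_features}},
    )


# ---------------------------------------------------------------------------
# GA descriptor-subset selection


@dataclass
class GAConfig:
    """Genetic-algorithm settings for descriptor subset selection.

    Fitness is the mean inner-CV AUC of a baseline classifier restricted
    to the candidate subset. Defaults are conventional GA settings; the
    selector is deterministic for a fixed seed.
    """

    population_size: int = 50
    generations: int = 30
    subset_size_target: int = 20
    crossover_rate: float = 0.7
    mutation_rate: float = 0.05
    tournament_size: int = 3
    elitism: int = 1
    inner_folds: int = 5
    fitness: str = "inner_cv_auc"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("population_size", "generations", "subset_size_target",
                     "tournament_size", "inner_folds"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("crossover_rate", "mutation_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


def _default_ga_estimator(seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)


def _subset_fitness(
    X: np.ndarray,
    y: np.ndarray,
    subset: tuple[int, ...],
    cfg: GAConfig,
    estimator_factory: Callable[[int], object],
    cache: dict,
) -> float:
    if subset in cache:
        return cache[subset]
    Xs = X[:, list(subset)]
    skf = StratifiedKFold(n_splits=cfg.inner_folds, shuffle=True, random_state=cfg.seed)
    aucs = []
    for train, test in skf.split(Xs, y):
        clf = estimator_factory(cfg.seed)
        clf.fit(Xs[train], y[train])
        scores = clf.predict_proba(Xs[test])[:, 1]
        aucs.append(roc_auc_score(y[test], scores))
    fit = float(np.mean(aucs))
    cache[subset] = fit
    return fit


def ga_select_features(
    m: FeatureMatrix,
    labels: Sequence[int],
    cfg: GAConfig | None = None,
    estimator_factory: Callable[[int], object] | None = None,
) -> list[str]:
    """Select a descriptor subset by a genetic algorithm.

    Individuals are fixed-size index subsets (size
    ``cfg.subset_size_target``); selection is tournament, crossover
    resamples from the union of two parents, mutation swaps single genes
    for unused features, and the elite individual survives unchanged.
    Returns the selected feature names (original matrix order).
    """
    cfg = cfg or GAConfig()
    estimator_factory = estimator_factory or _default_ga_estimator
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    if m.n_compounds != len(y):
        raise ValueError("labels must align with matrix rows")

    p = m.n_features
    k = cfg.subset_size_target
    if k >= p:
        return list(m.feature_names)

    rng = np.random.default_rng(cfg.seed)
    X = m.values
    cache: dict[tuple[int, ...], float] = {}

    def fitness(ind: tuple[int, ...]) -> float:
        return _subset_fitness(X, y, ind, cfg, estimator_factory, cache)

    def make_individual() -> tuple[int, ...]:
        return tuple(sorted(rng.choice(p, size=k, replace=False).tolist()))

    population = [make_individual() for _ in range(cfg.population_size)]

    def tournament() -> tuple[int, ...]:
        idx = rng.integers(0, len(population), size=cfg.tournament_size)
        return max((population[i] for i in idx), key=fitness)

    def crossover(a: tuple[int, ...], b: tuple[int, ...]) -> tuple[int, ...]:
        union = sorted(set(a) | set(b))
        child = rng.choice(len(union), size=k, replace=False)
        return tuple(sorted(union[i] for i in child))

    def mutate(ind: tuple[int, ...]) -> tuple[int, ...]:
        genes = list(ind)
        outside = [j for j in range(p) if j not in set(genes)]
        for g in range(k):
            if outside and rng.random() < cfg.mutation_rate:
                swap = int(rng.integers(0, len(outside)))
                genes[g], outside[swap] = outside[swap], genes[g]
        return tuple(sorted(genes))

    for _ in range(cfg.generations):
        ranked = sorted(population, key=fitness, reverse=True)
        next_pop = ranked[: cfg.elitism]
        while len(next_pop) < cfg.population_size:
            parent_a = tournament()
            if rng.random() < cfg.crossover_rate:
                parent_b = tournament()
                child = crossover(parent_a, parent_b)
            else:
                child = parent_a
            next_pop.append(mutate(child))
        population = next_pop

    best = max(population, key=fitness)
    return [m.feature_names[j] for j in best]


# ---------------------------------------------------------------------------
# Fingerprints


def compute_fingerprint(
    record: MoleculeRecord | Chem.Mol | str,
    kind: str,
    radius: int = 2,
    nbits: int = 2048,
) -> np.ndarray:
    """One binary fingerprint vector for one molecule.

    - ``maccs``: 166 keyed bits (radius/nbits ignored),
    - ``path_fp``: Daylight-style hashed linear paths up to length 7,
    - ``ecfp``/``fcfp``: hashed circular fingerprints; the common names
      map radius as ECFP2 -> 1, ECFP4 -> 2, ECFP6 -> 3.

    Deterministic: bit-identical across runs for fixed inputs.
    """
    mol = _as_mol(record)
    if kind == "maccs":
        bv = MACCSkeys.GenMACCSKeys(mol)
        # RDKit allocates 167 positions; bit 0 is a never-set placeholder.
        return np.array([bv.GetBit(i) for i in range(1, 167)], dtype=np.uint8)
    if kind == "path_fp":
        gen = rdFingerprintGenerator.GetRDKitFPGenerator(maxPath=7, fpSize=nbits)
        return gen.GetFingerprintAsNumPy(mol).astype(np.uint8)
    if kind in ("ecfp", "fcfp"):
        if radius not in (1, 2, 3):
            raise ValueError("circular fingerprint radius must be 1, 2 or 3")
        kwargs = {}
        if kind == "fcfp":
            kwargs["atomInvariantsGenerator"] = (
                rdFingerprintGenerator.GetMorganFeatureAtomInvGen()
            )
        gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=nbits, **kwargs
        )
        return gen.GetFingerprintAsNumPy(mol).astype(np.uint8)
    raise ValueError(f"unknown fingerprint kind {kind!r}")


def compute_fingerprint_matrix(
    records: Sequence[MoleculeRecord | Chem.Mol | str],
    kind: str,
    radius: int = 2,
    nbits: int = 2048,
) -> FeatureMatrix:
    """Stack per-molecule fingerprints into a binary FeatureMatrix."""
    rows = [compute_fingerprint(r, kind, radius=radius, nbits=nbits) for r in records]
    length = 166 if kind == "maccs" else nbits
    values = np.vstack(rows) if rows else np.empty((0, length))
    prefix = {"maccs": "maccs", "path_fp": "path", "ecfp": f"ecfp{2 * radius}",
              "fcfp": f"fcfp{2 * radius}"}[kind]
    return FeatureMatrix(
        values=values.astype(float),
        feature_names=[f"{prefix}_{i}" for i in range(values.shape[1])],
        kind=kind,
        binary=True,
        compound_ids=[_record_id(r, i) for i, r in enumerate(records)],
        meta={"radius": radius, "nbits": nbits} if kind != "maccs" else {},
    )


# ---------------------------------------------------------------------------
# Chemotypes


@dataclass
class ChemotypeSet:
    """Ordered named SMARTS patterns; order defines fingerprint bit order."""

    entries: list[tuple[str, str]]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("chemotype names must be unique")
        self._patterns: list[Chem.Mol] = []
        for name, smarts in self.entries:
            patt = Chem.MolFromSmarts(smarts)
            if patt is None:
                raise ValueError(f"SMARTS for {name!r} does not compile: {smarts!r}")
            self._patterns.append(patt)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.entries]

    @property
    def patterns(self) -> list[Chem.Mol]:
        return list(self._patterns)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ChemotypeSet":
        """Load a two-column ``name<TAB>SMARTS`` file; '#' starts a comment."""
        entries = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"malformed chemotype line: {line!r}")
            entries.append((parts[0].strip(), parts[1].strip()))
        return cls(entries=entries)

    @classmethod
    def default(cls) -> "ChemotypeSet":
        """The bundled genotoxicity-alert SMARTS set (~30 patterns)."""
        ref = importlib.resources.files("mnqsar.data") / "chemotypes_default.tsv"
        with importlib.resources.as_file(ref) as path:
            return cls.from_tsv(path)


def compute_chemotype_fingerprint(
    record: MoleculeRecord | Chem.Mol | str, cts: ChemotypeSet
) -> np.ndarray:
    """Bit i = 1 iff chemotype i has at least one substructure match."""
    mol = _as_mol(record)
    return np.array(
        [1 if mol.HasSubstructMatch(p) else 0 for p in cts.patterns], dtype=np.uint8
    )


def compute_chemotype_matrix(
    records: Sequence[MoleculeRecord | Chem.Mol | str], cts: ChemotypeSet
) -> FeatureMatrix:
    rows = [compute_chemotype_fingerprint(r, cts) for r in records]
    values = np.vstack(rows) if rows else np.empty((0, len(cts)))
    return FeatureMatrix(
        values=values.astype(float),
        feature_names=cts.names,
        kind="chemotype",
        binary=True,
        compound_ids=[_record_id(r, i) for i, r in enumerate(records)],
    )
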