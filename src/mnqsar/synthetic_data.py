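"""Synthetic datasets with planted structure-activity signal.

The real micronucleus datasets are not redistributable, so every stage
of the pipeline is exercised on generated data that reproduces their
statistical shape: imbalanced binary labels (~70/30 positive for the
in-vitro-like endpoint, ~32/68 for the in-vivo-like one), a minority of
compounds carrying enriched substructures at controllable
class-conditional prevalences, and paired endpoints sharing one
compound set.

Two generators are provided: a pure feature-space generator (binary
chemotype-style matrices from Bernoulli draws) and a molecule generator
that assembles valid SMILES from a template grammar (benzene /
cyclohexane / alkyl-chain scaffolds x functional-group fragments) so
that planted substructures are discoverable by real SMARTS matching and
every emitted structure survives curation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .curation import MoleculeRecord
from .featurization import FeatureMatrix


@dataclass(frozen=True)
class PlantedChemotype:
    """One enriched substructure: class-conditional carry probabilities."""

    name: str
    prevalence_in_positives: float
    prevalence_in_negatives: float

    def __post_init__(self) -> None:
        for p in (self.prevalence_in_positives, self.prevalence_in_negatives):
            if not 0 <= p <= 1:
                raise ValueError("prevalences must be in [0, 1]")

    @property
    def expected_odds_ratio(self) -> float:
        """Closed-form odds ratio of the generating Bernoulli model."""
        pp, pn = self.prevalence_in_positives, self.prevalence_in_negatives
        return (pp * (1 - pn)) / ((1 - pp) * pn)


@dataclass
class SyntheticSpec:
    """Conditions for one synthetic endpoint.

    ``positive_fraction`` defaults to the in-vitro-like 70% positive
    split; pass 0.32 for an in-vivo-like endpoint. Noise features are
    independent of the label at a common prevalence.
    """

    n_compounds: int = 1000
    positive_fraction: float = 0.70
    planted: list[PlantedChemotype] = field(default_factory=list)
    n_noise_features: int = 20
    noise_prevalence: float = 0.10
    label_noise_rate: float = 0.0
    mutually_exclusive_planting: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 10:
            raise ValueError("n_compounds must be >= 10")
        if not 0 <= self.positive_fraction <= 1:
            raise ValueError("positive_fraction must be in [0, 1]")
        if not 0 <= self.label_noise_rate <= 1:
            raise ValueError("label_noise_rate must be in [0, 1]")
        if self.mutually_exclusive_planting:
            for attr in ("prevalence_in_positives", "prevalence_in_negatives"):
                if sum(getattr(ct, attr) for ct in self.planted) > 1:
                    raise ValueError(
                        "mutually exclusive planting needs per-class "
                        "prevalences summing to <= 1"
                    )


def _draw_labels(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    n_pos = round(spec.n_compounds * spec.positive_fraction)
    labels = np.zeros(spec.n_compounds, dtype=int)
    labels[:n_pos] = 1
    rng.shuffle(labels)
    for ct in spec.planted:
        if ct.prevalence_in_positives > 0 and n_pos == 0:
            raise ValueError(f"{ct.name}: positive prevalence but no positives")
        if ct.prevalence_in_negatives > 0 and n_pos == spec.n_compounds:
            raise ValueError(f"{ct.name}: negative prevalence but no negatives")
    return labels


def _plant_bits(
    labels: np.ndarray, ct: PlantedChemotype, rng: np.random.Generator
) -> np.ndarray:
    prev = np.where(labels == 1, ct.prevalence_in_positives,
                    ct.prevalence_in_negatives)
    return (rng.random(len(labels)) < prev).astype(int)


def _plant_bits_exclusive(
    labels: np.ndarray,
    planted: list[PlantedChemotype],
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """At most one planted chemotype per compound.

    A single uniform draw per compound is cut into per-chemotype
    intervals of width equal to each class-conditional prevalence, so
    every chemotype's marginal prevalence is preserved exactly while
    carriers never overlap (needed when per-chemotype label redraws must
    be unambiguous, e.g. paired-endpoint generation).
    """
    n = len(labels)
    u = rng.random(n)
    bits = {ct.name: np.zeros(n, dtype=int) for ct in planted}
    lower = np.zeros(n)
    for ct in planted:
        width = np.where(labels == 1, ct.prevalence_in_positives,
                         ct.prevalence_in_negatives)
        bits[ct.name] = ((u >= lower) & (u < lower + width)).astype(int)
        lower = lower + width
    return bits


def _apply_label_noise(
    labels: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    if rate <= 0:
        return labels
    flip = rng.random(len(labels)) < rate
    return np.where(flip, 1 - labels, labels)


def generate_feature_dataset(
    spec: SyntheticSpec,
) -> tuple[FeatureMatrix, np.ndarray]:
    """Binary chemotype-style feature matrix plus labels.

    Labels match ``positive_fraction`` exactly (before optional label
    noise); planted bits are independent Bernoulli draws at the
    class-conditional prevalences; noise features are label-independent.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    labels = _draw_labels(spec, rng)
    columns = []
    names = []
    if spec.mutually_exclusive_planting:
        exclusive = _plant_bits_exclusive(labels, spec.planted, rng)
        for ct in spec.planted:
            columns.append(exclusive[ct.name])
            names.append(ct.name)
    else:
        for ct in spec.planted:
            columns.append(_plant_bits(labels, ct, rng))
            names.append(ct.name)
    for j in range(spec.n_noise_features):
        columns.append((rng.random(spec.n_compounds) < spec.noise_prevalence)
                       .astype(int))
        names.append(f"noise_{j}")
    values = (np.column_stack(columns) if columns
              else np.empty((spec.n_compounds, 0)))
    labels = _apply_label_noise(labels, spec.label_noise_rate, rng)
    fm = FeatureMatrix(
        values=values.astype(float),
        feature_names=names,
        kind="chemotype",
        binary=True,
        compound_ids=[f"syn{i:05d}" for i in range(spec.n_compounds)],
        meta={"generator": "feature", "seed": spec.seed},
    )
    return fm, labels


# ---------------------------------------------------------------------------
# Molecule grammar

#: Attachable fragment per plantable chemotype. Ring-closure digits 7-9
#: keep fragments safe to splice into scaffold templates that use 1.
PLANTED_FRAGMENTS: dict[str, str] = {
    "carbamate": "OC(N)=O",
    "nitroso": "N=O",
    "sulfonic_ester_alkyl": "COS(C)(=O)=O",
    "aziridine": "N7CC7",
    "quinone": "C7=CC(=O)C=CC7=O",
    "alkyl_chloride": "CCCl",
    "alkyl_bromide": "CCBr",
}

#: Label-independent decoration; deliberately free of N, S and heavy
#: halogens so inert parts can never realize a plantable alert.
_INERT_SUBSTITUENTS = ("", "C", "CC", "CCC", "F", "OC", "CO", "C(C)C")

#: Scaffold templates with two substituent slots and a chain tail slot.
_SCAFFOLDS = (
    "c1cc{a1}cc{a2}c1{t}",
    "C1CC{a1}CC{a2}C1{t}",
    "C{a1}CCC{a2}C{t}",
)


def _branch(fragment: str) -> str:
    return f"({fragment})" if fragment else ""


def _assemble(template: str, a1: str, a2: str, tail: str) -> str:
    return template.format(a1=_branch(a1), a2=_branch(a2), t=tail)


def generate_molecule_dataset(
    spec: SyntheticSpec, endpoint: str = "mn_in_vitro"
) -> list[MoleculeRecord]:
    """Valid, curation-proof molecules with planted substructures.

    Each compound is assembled from a scaffold template plus fragments;
    a planted fragment is attached with its class-conditional
    prevalence. Emitted structures are pairwise distinct by InChIKey, so
    the whole dataset round-trips through curation without losses.
    """
    unknown = [ct.name for ct in spec.planted if ct.name not in PLANTED_FRAGMENTS]
    if unknown:
        raise ValueError(
            f"no grammar fragment for planted chemotype(s) {unknown}; "
            f"available: {sorted(PLANTED_FRAGMENTS)}"
        )
    rng = np.random.default_rng(spec.seed)
    labels = _draw_labels(spec, rng)
    carries = {ct.name: _plant_bits(labels, ct, rng) for ct in spec.planted}
    labels = _apply_label_noise(labels, spec.label_noise_rate, rng)

    records: list[MoleculeRecord] = []
    seen_keys: set[str] = set()
    for i in range(spec.n_compounds):
        fragments = [PLANTED_FRAGMENTS[ct.name] for ct in spec.planted
                     if carries[ct.name][i]]
        template = _SCAFFOLDS[int(rng.integers(0, len(_SCAFFOLDS)))]
        slots = (fragments + [
            str(rng.choice(_INERT_SUBSTITUENTS)),
            str(rng.choice(_INERT_SUBSTITUENTS)),
        ])[:2]
        tail = "C" * int(rng.integers(0, 6))
        for _ in range(300):
            smiles = _assemble(template, slots[0], slots[1], tail)
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:  # pragma: no cover - grammar guarantees validity
                raise RuntimeError(f"grammar produced invalid SMILES {smiles!r}")
            key = Chem.MolToInchiKey(mol)
            if key not in seen_keys:
                break
            tail += "C"
        else:  # pragma: no cover
            raise RuntimeError("could not generate a structurally unique compound")
        seen_keys.add(key)
        records.append(
            MoleculeRecord(
                record_id=f"syn{i:05d}",
                smiles=Chem.MolToSmiles(mol),
                label=int(labels[i]),
                endpoint=endpoint,
                source="synthetic",
            )
        )
    return records


#: Generator defaults for the end-to-end modeling scenario: two strong
#: structural alerts, prevalences chosen from the closed-form AUC
#: ceiling of two independent alert bits so the planted signal is
#: learnable to a high-AUC level (see docs/methods.md).
def smoke_scenario_spec(
    n_compounds: int = 800, seed: int = 0
) -> SyntheticSpec:
    return SyntheticSpec(
        n_compounds=n_compounds,
        positive_fraction=0.70,
        planted=[
            PlantedChemotype("carbamate", 0.55, 0.05),
            PlantedChemotype("nitroso", 0.50, 0.05),
        ],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Paired endpoints


@dataclass
class PairedSpec:
    """Shared-compound pair of endpoints with target cross-endpoint PPVs.

    Endpoint A is generated from ``spec_a``; endpoint B reuses the same
    compounds and redraws labels so that, for every planted chemotype in
    ``cross_map``, the expected PPV of that chemotype in B equals the
    mapped target. Non-carriers are labeled to hit
    ``positive_fraction_b`` overall in expectation.
    """

    spec_a: SyntheticSpec
    positive_fraction_b: float = 0.32
    cross_map: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, ppv in self.cross_map.items():
            if not 0 <= ppv <= 1:
                raise ValueError(f"cross_map PPV for {name!r} must be in [0, 1]")


def generate_paired_endpoints(
    pspec: PairedSpec,
) -> tuple[FeatureMatrix, np.ndarray, np.ndarray]:
    """One compound set, two label vectors (endpoints A and B)."""
    fm, labels_a = generate_feature_dataset(pspec.spec_a)
    rng = np.random.default_rng(pspec.spec_a.seed + 1)
    n = fm.n_compounds

    target_ppv = np.full(n, np.nan)
    for name, ppv in pspec.cross_map.items():
        if name not in fm.feature_names:
            raise ValueError(f"cross_map chemotype {name!r} not generated")
        j = fm.feature_names.index(name)
        carrier = fm.values[:, j] == 1
        # first matching chemotype wins for multi-carriers
        target_ppv = np.where(carrier & np.isnan(target_ppv), ppv, target_ppv)

    is_carrier = ~np.isnan(target_ppv)
    n_carrier = int(is_carrier.sum())
    expected_carrier_pos = float(np.nansum(target_ppv))
    n_pos_b = pspec.positive_fraction_b * n
    n_rest = n - n_carrier
    if n_rest > 0:
        p_rest = (n_pos_b - expected_carrier_pos) / n_rest
    else:
        p_rest = 0.0
    if not 0 <= p_rest <= 1:
        raise ValueError(
            "cross_map PPVs are unattainable given endpoint B's class balance"
        )
    draw = rng.random(n)
    labels_b = np.where(
        is_carrier, (draw < np.nan_to_num(target_ppv)).astype(int),
        (draw < p_rest).astype(int),
    )
    return fm, labels_a, labels_b.astype(int)
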