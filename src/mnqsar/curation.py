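"""Chemical-record curation for micronucleus QSAR datasets.

Raw structure-activity records (SMILES + binary micronucleus call +
endpoint tag) are standardized and deduplicated before any statistics or
modeling: counter-ions are stripped, net charges neutralized, and
compounds outside the organic QSAR domain (mixtures, polymers,
inorganics, organometallics) are rejected with an itemized reason.
Identity is the full 27-character InChIKey; duplicate records within an
endpoint are merged when their labels agree and otherwise resolved by an
explicit conflict policy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)

# InChI generation is chatty about charge/proton bookkeeping on salts;
# those warnings are expected for the inputs this module exists to clean.
RDLogger.DisableLog("rdApp.warning")

ENDPOINTS = ("mn_in_vitro", "mn_in_vivo_mouse", "mn_in_vivo_rat")

REJECTION_CODES = ("mixture", "polymer", "inorganic", "organometallic", "unparseable")

#: Elements allowed in the organic QSAR domain. Anything outside this set
#: is treated as a metal/metalloid and triggers rejection. Si is allowed:
#: organosilicons are conventionally kept in organic-subset QSAR.
ORGANIC_ELEMENTS = frozenset((1, 5, 6, 7, 8, 9, 14, 15, 16, 17, 34, 35, 53))

Policy = Literal["exclude_conflicts", "prefer_compliant"]


@dataclass(frozen=True)
class RejectionReason:
    """Why a structure was removed during curation."""

    code: str
    detail: str = ""

    def __post_init__(self) -> None:
        if self.code not in REJECTION_CODES:
            raise ValueError(f"unknown rejection code {self.code!r}")


@dataclass(frozen=True)
class Standardized:
    """Canonical neutral parent structure plus its identity key."""

    canonical_smiles: str
    inchikey: str


@dataclass
class MoleculeRecord:
    """One chemical with structure, identity and a binary activity label.

    ``label`` is 1 for micronucleus-positive, 0 for negative. ``inchikey``
    and ``canonical_smiles`` are filled in by :func:`standardize_records`;
    deduplication refuses records that have not been standardized.
    """

    record_id: str
    smiles: str
    label: int
    endpoint: str
    cas: str | None = None
    name: str | None = None
    source: str = ""
    guideline_compliant: bool | None = None
    canonical_smiles: str | None = None
    inchikey: str | None = None

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        if self.endpoint not in ENDPOINTS:
            raise ValueError(
                f"endpoint must be one of {ENDPOINTS}, got {self.endpoint!r}"
            )


_UNCHARGER = rdMolStandardize.Uncharger()


def _contains_metal(mol: Chem.Mol) -> list[str]:
    return sorted(
        {
            a.GetSymbol()
            for a in mol.GetAtoms()
            if a.GetAtomicNum() not in ORGANIC_ELEMENTS and a.GetAtomicNum() != 0
        }
    )


def standardize_structure(smiles: str) -> Standardized | RejectionReason:
    """Standardize one SMILES to its neutral organic parent.

    Counter-ion fragments (no carbon) are stripped, the remaining
    fragment is charge-neutralized where chemically valid, and the
    canonical SMILES plus full InChIKey of the result are returned.
    Structures outside the organic domain come back as a
    :class:`RejectionReason` instead:

    - unparseable SMILES -> ``unparseable``
    - wildcard/repeat-unit atoms -> ``polymer``
    - no carbon-containing fragment -> ``inorganic``
    - two or more carbon fragments after salt stripping -> ``mixture``
    - metal atom in the organic parent -> ``organometallic``

    Deterministic: identical input yields an identical result.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        return RejectionReason("unparseable", "empty SMILES")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return RejectionReason("unparseable", f"RDKit could not parse {smiles!r}")
    if any(a.GetAtomicNum() == 0 for a in mol.GetAtoms()):
        return RejectionReason("polymer", "wildcard atom (repeat-unit notation)")

    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    organic = [f for f in frags if any(a.GetAtomicNum() == 6 for a in f.GetAtoms())]
    if not organic:
        metals = _contains_metal(mol)
        detail = "no carbon atoms" + (f"; metals present: {','.join(metals)}" if metals else "")
        return RejectionReason("inorganic", detail)
    if len(organic) >= 2:
        return RejectionReason(
            "mixture", f"{len(organic)} organic fragments after salt stripping"
        )

    parent = organic[0]
    metals = _contains_metal(parent)
    if metals:
        return RejectionReason("organometallic", f"metal atoms: {','.join(metals)}")

    parent = _UNCHARGER.uncharge(parent)
    Chem.SanitizeMol(parent)
    canonical = Chem.MolToSmiles(parent)
    inchikey = Chem.MolToInchiKey(parent)
    if not inchikey:
        return RejectionReason("unparseable", "InChIKey generation failed")
    return Standardized(canonical_smiles=canonical, inchikey=inchikey)


def standardize_records(
    records: Iterable[MoleculeRecord],
) -> tuple[list[MoleculeRecord], list[tuple[str, RejectionReason]]]:
    """Standardize every record; return (kept records, rejections).

    Kept records carry ``canonical_smiles`` and ``inchikey``; each
    rejected input appears exactly once in the rejection list keyed by
    its ``record_id``.
    """
    kept: list[MoleculeRecord] = []
    rejected: list[tuple[str, RejectionReason]] = []
    for rec in records:
        result = standardize_structure(rec.smiles)
        if isinstance(result, RejectionReason):
            rejected.append((rec.record_id, result))
            logger.info("rejected %s: %s (%s)", rec.record_id, result.code, result.detail)
        else:
            kept.append(
                replace(
                    rec,
                    canonical_smiles=result.canonical_smiles,
                    inchikey=result.inchikey,
                )
            )
    return kept, rejected


@dataclass
class DedupEntry:
    """One deduplication event: a merge of agreeing duplicates or a conflict."""

    inchikey: str
    endpoint: str
    record_ids: tuple[str, ...]
    labels: tuple[int, ...]
    resolution: str  # merged | conflict_excluded | conflict_kept_compliant


@dataclass
class DedupReport:
    merges: list[DedupEntry] = field(default_factory=list)
    conflicts: list[DedupEntry] = field(default_factory=list)

    @property
    def n_conflicts(self) -> int:
        return len(self.conflicts)


def deduplicate_records(
    records: Sequence[MoleculeRecord],
    policy: Policy = "exclude_conflicts",
) -> tuple[list[MoleculeRecord], DedupReport]:
    """Collapse records to one per (InChIKey, endpoint).

    Duplicates with identical labels merge to the first record (by
    ``record_id`` order). Label conflicts are resolved per ``policy``:

    - ``exclude_conflicts``: the compound is dropped and the conflict logged.
    - ``prefer_compliant``: if exactly one duplicate has
      ``guideline_compliant=True`` it is kept, otherwise the compound is
      dropped.

    Output order is deterministic (sorted by InChIKey, then endpoint).
    """
    if policy not in ("exclude_conflicts", "prefer_compliant"):
        raise ValueError(f"unknown policy {policy!r}")
    for rec in records:
        if not rec.inchikey:
            raise ValueError(
                f"record {rec.record_id!r} has no InChIKey; standardize before deduplicating"
            )

    groups: dict[tuple[str, str], list[MoleculeRecord]] = {}
    for rec in records:
        groups.setdefault((rec.inchikey, rec.endpoint), []).append(rec)

    curated: list[MoleculeRecord] = []
    report = DedupReport()
    for (key, endpoint), group in sorted(groups.items()):
        group = sorted(group, key=lambda r: r.record_id)
        labels = {r.label for r in group}
        ids = tuple(r.record_id for r in group)
        labs = tuple(r.label for r in group)
        if len(labels) == 1:
            curated.append(group[0])
            if len(group) > 1:
                report.merges.append(
                    DedupEntry(key, endpoint, ids, labs, "merged")
                )
        elif policy == "exclude_conflicts":
            report.conflicts.append(
                DedupEntry(key, endpoint, ids, labs, "conflict_excluded")
            )
        else:  # prefer_compliant
            compliant = [r for r in group if r.guideline_compliant]
            if len(compliant) == 1:
                curated.append(compliant[0])
                report.conflicts.append(
                    DedupEntry(key, endpoint, ids, labs, "conflict_kept_compliant")
                )
            else:
                report.conflicts.append(
                    DedupEntry(key, endpoint, ids, labs, "conflict_excluded")
                )
    return curated, report


@dataclass
class CurationResult:
    curated: list[MoleculeRecord]
    rejections: list[tuple[str, RejectionReason]]
    dedup: DedupReport

    @property
    def n_curated(self) -> int:
        return len(self.curated)


def curate_records(
    records: Iterable[MoleculeRecord],
    policy: Policy = "exclude_conflicts",
) -> CurationResult:
    """Full curation pipeline: standardize then deduplicate.

    Idempotent: running the output through again changes nothing.
    """
    standardized, rejections = standardize_records(records)
    curated, dedup = deduplicate_records(standardized, policy=policy)
    return CurationResult(curated=curated, rejections=rejections, dedup=dedup)


# ---------------------------------------------------------------------------
# I/O


_CSV_COLUMNS = {
    "smiles": "smiles",
    "label": "label",
    "endpoint": "endpoint",
    "cas": "cas",
    "name": "name",
    "source": "source",
    "compliant": "guideline_compliant",
}


def read_records_csv(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    delimiter: str = ",",
) -> list[MoleculeRecord]:
    """Read molecule records from CSV.

    ``column_map`` maps the canonical column names (smiles, label,
    endpoint, cas, name, source, compliant) to the file's actual headers
    when they differ.
    """
    colmap = dict(_CSV_COLUMNS)
    if column_map:
        for canon, actual in column_map.items():
            if canon not in _CSV_COLUMNS:
                raise ValueError(f"unknown canonical column {canon!r}")
            colmap[canon] = actual
    df = pd.read_csv(path, sep=delimiter, dtype={colmap["smiles"]: str})
    for required in ("smiles", "label", "endpoint"):
        if colmap[required] not in df.columns:
            raise ValueError(f"missing required column {colmap[required]!r}")
    records = []
    for i, row in df.iterrows():
        def get(canon: str):
            col = colmap[canon]
            if col not in df.columns:
                return None
            val = row[col]
            return None if pd.isna(val) else val

        compliant = get("compliant")
        if compliant is not None:
            compliant = str(compliant).strip().lower() in ("1", "true", "yes", "y")
        records.append(
            MoleculeRecord(
                record_id=str(get("name") or f"row{i}") + f"#{i}",
                smiles=str(row[colmap["smiles"]]),
                label=int(row[colmap["label"]]),
                endpoint=str(row[colmap["endpoint"]]),
                cas=None if get("cas") is None else str(get("cas")),
                name=None if get("name") is None else str(get("name")),
                source="" if get("source") is None else str(get("source")),
                guideline_compliant=compliant,
            )
        )
    return records


def read_records_sdf(
    path: str | Path,
    label_prop: str = "label",
    endpoint_prop: str = "endpoint",
    endpoint: str | None = None,
) -> list[MoleculeRecord]:
    """Read molecule records from an SDF file with a label property.

    ``endpoint`` overrides the per-molecule endpoint property when all
    records in the file share one endpoint.
    """
    records = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=False)
    for i, mol in enumerate(supplier):
        if mol is None:
            # keep the slot so curation can report it as unparseable
            records.append(
                MoleculeRecord(
                    record_id=f"sdf{i}",
                    smiles="",
                    label=0,
                    endpoint=endpoint or ENDPOINTS[0],
                )
            )
            continue
        props = mol.GetPropsAsDict()
        ep = endpoint or str(props.get(endpoint_prop, ""))
        records.append(
            MoleculeRecord(
                record_id=str(props.get("_Name") or f"sdf{i}") + f"#{i}",
                smiles=Chem.MolToSmiles(Chem.Mol(mol)),
                label=int(props[label_prop]),
                endpoint=ep,
                name=str(props.get("_Name")) or None,
            )
        )
    return records


def write_curated_csv(records: Sequence[MoleculeRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "record_id": [r.record_id for r in records],
            "smiles": [r.canonical_smiles for r in records],
            "inchikey": [r.inchikey for r in records],
            "label": [r.label for r in records],
            "endpoint": [r.endpoint for r in records],
            "cas": [r.cas for r in records],
            "name": [r.name for r in records],
            "source": [r.source for r in records],
        }
    )
    df.to_csv(path, index=False)


def write_rejection_csv(result: CurationResult, path: str | Path) -> None:
    """Itemize every dropped input: structural rejections, conflicts, merges."""
    rows = []
    for record_id, reason in result.rejections:
        rows.append(
            {"record_id": record_id, "kind": "rejection", "code": reason.code,
             "detail": reason.detail}
        )
    for entry in result.dedup.conflicts:
        rows.append(
            {"record_id": ";".join(entry.record_ids), "kind": "conflict",
             "code": entry.resolution,
             "detail": f"{entry.inchikey}/{entry.endpoint} labels={entry.labels}"}
        )
    for entry in result.dedup.merges:
        rows.append(
            {"record_id": ";".join(entry.record_ids), "kind": "merge",
             "code": entry.resolution,
             "detail": f"{entry.inchikey}/{entry.endpoint} kept={entry.record_ids[0]}"}
        )
    pd.DataFrame(rows, columns=["record_id", "kind", "code", "detail"]).to_csv(
        path, index=False
    )
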