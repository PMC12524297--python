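"""SMILES → 516-dimensional feature vectors.

Each molecule is encoded as a 512-bit Morgan (circular) fingerprint of
radius 2 concatenated with four physicochemical descriptors, in the fixed
order [MolWt, MolLogP, NumHDonors, NumHAcceptors].  Features are z-scored
(population statistics) with parameters fitted on training data only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdFingerprintGenerator

# RDKit writes parse errors to its own log; we report them through rejects.
RDLogger.DisableLog("rdApp.error")

logger = logging.getLogger(__name__)

N_FINGERPRINT_BITS = 512
FINGERPRINT_RADIUS = 2
DESCRIPTOR_NAMES = ("MolWt", "MolLogP", "NumHDonors", "NumHAcceptors")
N_FEATURES = N_FINGERPRINT_BITS + len(DESCRIPTOR_NAMES)

#: Column manifest for the 516-dim feature matrix, fingerprint block first.
FEATURE_COLUMNS: tuple[str, ...] = tuple(
    f"fp_{i}" for i in range(N_FINGERPRINT_BITS)
) + DESCRIPTOR_NAMES


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


class FeaturizationError(ValueError):
    """Raised when descriptor or fingerprint computation fails."""


@dataclass(frozen=True)
class MoleculeRecord:
    """One compound: opaque id, SMILES string, optional binary hazard label.

    label 1 = hazardous (positive class), 0 = non-hazardous (negative).
    """

    id: str
    smiles: str
    label: int | None = None

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(
                f"record {self.id!r}: label must be 0 or 1, got {self.label!r}"
            )


@dataclass(frozen=True)
class DescriptorVector:
    """The four global physicochemical descriptors, in fixed order."""

    mol_wt: float
    mol_logp: float
    num_h_donors: int
    num_h_acceptors: int

    def __post_init__(self) -> None:
        if self.mol_wt <= 0:
            raise ValueError(f"mol_wt must be positive, got {self.mol_wt}")
        if self.num_h_donors < 0 or self.num_h_acceptors < 0:
            raise ValueError("H-bond donor/acceptor counts must be non-negative")

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.mol_wt, self.mol_logp, self.num_h_donors, self.num_h_acceptors],
            dtype=np.float64,
        )


def parse_smiles(smiles: str) -> Chem.Mol:
    """Parse and canonicalize a SMILES string.

    The molecule is round-tripped through RDKit's canonical SMILES so that
    downstream features are invariant to input atom ordering.  Multi-fragment
    inputs (salts, counter-ions) are featurized as given but logged.

    Raises
    ------
    SmilesParseError
        If the string is empty or not valid SMILES.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    canonical = Chem.MolToSmiles(mol)
    if "." in canonical:
        logger.warning("multi-fragment SMILES featurized as given: %r", smiles)
    mol = Chem.MolFromSmiles(canonical)
    if mol is None:  # pragma: no cover - canonical SMILES always re-parses
        raise SmilesParseError(f"canonicalization failed for {smiles!r}")
    return mol


def morgan_fingerprint(
    mol: Chem.Mol,
    n_bits: int = N_FINGERPRINT_BITS,
    radius: int = FINGERPRINT_RADIUS,
) -> np.ndarray:
    """Circular (Morgan/ECFP-style) fingerprint as a {0,1} vector.

    Bit j is set iff some atom environment of bond radius ≤ `radius`
    hashes to position j.
    """
    if n_bits <= 0:
        raise ValueError(f"n_bits must be positive, got {n_bits}")
    if radius < 0:
        raise ValueError(f"radius must be non-negative, got {radius}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bv = gen.GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=np.uint8)
    arr[list(bv.GetOnBits())] = 1
    return arr


def compute_descriptors(mol: Chem.Mol) -> DescriptorVector:
    """Compute [MolWt, MolLogP, NumHDonors, NumHAcceptors] for a molecule."""
    try:
        return DescriptorVector(
            mol_wt=float(Descriptors.MolWt(mol)),
            mol_logp=float(Crippen.MolLogP(mol)),
            num_h_donors=int(Lipinski.NumHDonors(mol)),
            num_h_acceptors=int(Lipinski.NumHAcceptors(mol)),
        )
    except Exception as exc:  # RDKit failures surface as a typed rejection
        raise FeaturizationError(f"descriptor computation failed: {exc}") from exc


def build_feature_vector(fp: np.ndarray, desc: DescriptorVector) -> np.ndarray:
    """Concatenate fingerprint and descriptors into one 516-long raw vector."""
    fp = np.asarray(fp)
    if fp.shape != (N_FINGERPRINT_BITS,):
        raise ValueError(
            f"fingerprint must have shape ({N_FINGERPRINT_BITS},), got {fp.shape}"
        )
    return np.concatenate([fp.astype(np.float64), desc.to_array()])


def featurize_smiles(smiles: str) -> np.ndarray:
    """Convenience: SMILES → raw 516-dim feature vector."""
    mol = parse_smiles(smiles)
    return build_feature_vector(morgan_fingerprint(mol), compute_descriptors(mol))


@dataclass
class FeaturizationResult:
    """Feature matrix plus aligned ids/labels and a reject report."""

    X: np.ndarray                      # (n_ok, 516) raw features
    labels: np.ndarray | None          # (n_ok,) int labels, None if unlabeled
    ids: list[str]
    rejects: list[tuple[str, str]]     # (record id, reason)
    columns: tuple[str, ...] = FEATURE_COLUMNS


def featurize_dataset(records: Iterable[MoleculeRecord]) -> FeaturizationResult:
    """Featurize every record, routing failures to the reject report.

    Row order follows input order of the successfully featurized records;
    no record is silently dropped.
    """
    rows: list[np.ndarray] = []
    labels: list[int] = []
    ids: list[str] = []
    rejects: list[tuple[str, str]] = []
    any_labeled = False
    for rec in records:
        try:
            rows.append(featurize_smiles(rec.smiles))
        except (SmilesParseError, FeaturizationError) as exc:
            rejects.append((rec.id, str(exc)))
            continue
        ids.append(rec.id)
        if rec.label is not None:
            any_labeled = True
            labels.append(int(rec.label))
        else:
            labels.append(-1)
    X = np.array(rows, dtype=np.float64) if rows else np.empty((0, N_FEATURES))
    y = np.array(labels, dtype=np.int64) if any_labeled else None
    if y is not None and np.any(y < 0):
        raise ValueError("mixed labeled and unlabeled records in one dataset")
    return FeaturizationResult(X=X, labels=y, ids=ids, rejects=rejects)


@dataclass
class StandardizationParams:
    """Per-column z-score parameters, fitted on one named split.

    Uses population (denominator n) statistics.  Zero-variance columns keep
    sd = 1 so they standardize to a constant 0 instead of NaN; common for
    fingerprint bits that are never set in the training data.
    """

    mean: np.ndarray
    sd: np.ndarray
    fit_on: str = "train"
    constant_columns: np.ndarray = field(default_factory=lambda: np.array([], int))

    def to_json(self) -> str:
        return json.dumps(
            {
                "mean": self.mean.tolist(),
                "sd": self.sd.tolist(),
                "fit_on": self.fit_on,
                "constant_columns": self.constant_columns.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "StandardizationParams":
        obj = json.loads(text)
        return cls(
            mean=np.asarray(obj["mean"], dtype=np.float64),
            sd=np.asarray(obj["sd"], dtype=np.float64),
            fit_on=obj["fit_on"],
            constant_columns=np.asarray(obj["constant_columns"], dtype=np.int64),
        )


def fit_standardizer(X: np.ndarray, fit_on: str = "train") -> StandardizationParams:
    """Fit per-column mean/sd on a feature matrix (≥ 2 rows)."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError(f"need a 2-D matrix with ≥ 2 rows, got shape {X.shape}")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population (ddof=0)
    constant = np.flatnonzero(sd == 0.0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return StandardizationParams(mean=mean, sd=sd, fit_on=fit_on,
                                 constant_columns=constant)


def apply_standardizer(X: np.ndarray, p: StandardizationParams) -> np.ndarray:
    """Element-wise (x − μ)/σ."""
    X = np.asarray(X, dtype=np.float64)
    if X.shape[-1] != p.mean.shape[0]:
        raise ValueError(
            f"column count {X.shape[-1]} does not match fitted {p.mean.shape[0]}"
        )
    return (X - p.mean) / p.sd


def invert_standardizer(X_std: np.ndarray, p: StandardizationParams) -> np.ndarray:
    """Inverse transform x′·σ + μ."""
    X_std = np.asarray(X_std, dtype=np.float64)
    if X_std.shape[-1] != p.mean.shape[0]:
        raise ValueError(
            f"column count {X_std.shape[-1]} does not match fitted {p.mean.shape[0]}"
        )
    return X_std * p.sd + p.mean


def drop_feature_columns(
    X: np.ndarray,
    drop: Sequence[int],
    columns: Sequence[str] = FEATURE_COLUMNS,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Remove feature columns by index, returning matrix + reduced manifest."""
    keep = [i for i in range(X.shape[1]) if i not in set(drop)]
    return X[:, keep], tuple(columns[i] for i in keep)
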