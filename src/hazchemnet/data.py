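"""Dataset readers/writers, synthetic fixtures, config loading, run logging.

The real dataset (a table of id, SMILES, binary hazard label; 2428
hazardous vs 2712 non-hazardous compounds, positive:negative ratio ≈ 0.9)
is an optional input.  Everything in the package — pipeline runs and the
test suite — also works from two synthetic generators: a purely numeric
516-dim feature generator with class-separable structure, and a SMILES
table sampler drawing from a curated pool of real molecules.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ConfigError, TrainingConfig, dump_config, load_config  # noqa: F401 (re-exported surface)
from .featurize import (
    N_FEATURES,
    N_FINGERPRINT_BITS,
    MoleculeRecord,
)

logger = logging.getLogger(__name__)


class DatasetError(ValueError):
    """Raised for malformed dataset files (columns, labels, duplicates)."""


@dataclass(frozen=True)
class DatasetManifest:
    """Provenance + recounted class balance of a loaded dataset."""

    source: str                 # "supplementary" | "synthetic" | "user"
    n_positive: int
    n_negative: int
    checksum: str = ""

    @property
    def ratio(self) -> float:
        """Positive:negative ratio, recomputed from the counts."""
        if self.n_negative == 0:
            return float("inf")
        return self.n_positive / self.n_negative


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def read_dataset(
    path: str | Path,
    fmt: str | None = None,
    source: str = "user",
) -> tuple[list[MoleculeRecord], DatasetManifest]:
    """Read a labeled (or unlabeled) SMILES table.

    Formats: csv/tsv with a header containing id, smiles and optionally
    label; or a bare .smi file (``SMILES whitespace id`` per line, no
    labels, prediction mode only).  Offending rows are named in errors;
    duplicate SMILES with conflicting labels keep the first occurrence and
    log the conflict.
    """
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"dataset file not found: {path}")
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "smi":
        records = []
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip():
                continue
            fields = line.split()
            smiles = fields[0]
            rec_id = fields[1] if len(fields) > 1 else f"line{lineno}"
            records.append(MoleculeRecord(id=rec_id, smiles=smiles))
        if not records:
            raise DatasetError(f"empty dataset file: {path}")
        manifest = DatasetManifest(source=source, n_positive=0, n_negative=0,
                                   checksum=_sha256(path))
        return records, manifest
    if fmt not in ("csv", "tsv"):
        raise DatasetError(f"unsupported dataset format {fmt!r}")
    sep = "\t" if fmt == "tsv" else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        raise DatasetError(f"empty dataset file: {path}") from None
    df.columns = [c.strip().lower() for c in df.columns]
    missing = {"id", "smiles"} - set(df.columns)
    if missing:
        raise DatasetError(f"missing required column(s): {sorted(missing)}")
    if df.empty:
        raise DatasetError(f"dataset file has a header but no rows: {path}")
    has_label = "label" in df.columns
    if has_label:
        bad = df.index[~df["label"].isin([0, 1])].tolist()
        if bad:
            rows = ", ".join(str(i + 2) for i in bad[:10])  # 1-based + header
            raise DatasetError(
                f"non-binary label(s) on file row(s): {rows}"
                + (" …" if len(bad) > 10 else "")
            )
    dup_ids = df["id"].astype(str)[df["id"].astype(str).duplicated()].unique()
    if dup_ids.size:
        raise DatasetError(f"duplicate id(s): {', '.join(dup_ids[:10])}")

    records: list[MoleculeRecord] = []
    seen_smiles: dict[str, int] = {}
    for _, row in df.iterrows():
        label = int(row["label"]) if has_label else None
        smi = str(row["smiles"])
        if smi in seen_smiles:
            if label is not None and label != seen_smiles[smi]:
                logger.warning(
                    "duplicate SMILES %r with conflicting labels; "
                    "keeping first occurrence", smi)
            continue
        if label is not None:
            seen_smiles[smi] = label
        records.append(MoleculeRecord(id=str(row["id"]), smiles=smi,
                                      label=label))
    n_pos = sum(1 for r in records if r.label == 1)
    n_neg = sum(1 for r in records if r.label == 0)
    manifest = DatasetManifest(source=source, n_positive=n_pos,
                               n_negative=n_neg, checksum=_sha256(path))
    return records, manifest


def write_dataset(records: list[MoleculeRecord], path: str | Path) -> None:
    """Write records as a CSV with columns id, smiles, label."""
    pd.DataFrame(
        {"id": [r.id for r in records],
         "smiles": [r.smiles for r in records],
         "label": [r.label for r in records]}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Synthetic feature generator (bypasses chemistry)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the class-separable synthetic feature generator.

    Two Gaussian classes (noise_sd each) differ by `class_separation` on
    `n_informative` dimensions; the first 512 dimensions are then
    binarized by thresholding at 0 to mimic fingerprint bits.  Defaults
    give a high-signal dataset (separation 3σ on 20 dimensions) that a
    working pipeline should classify almost perfectly.
    """

    n_per_class: int = 300
    class_separation: float = 3.0
    n_informative: int = 20
    noise_sd: float = 1.0
    seed: int = 0
    n_features: int = N_FEATURES
    binarize_bits: bool = True
    informative_dims: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.class_separation < 0:
            raise ValueError("class_separation must be non-negative")
        if self.n_informative > self.n_features:
            raise ValueError("n_informative exceeds feature dimension")


@dataclass
class SyntheticFeatures:
    X: np.ndarray                      # (2·n_per_class, n_features) raw
    y: np.ndarray                      # binary labels
    informative_dims: np.ndarray       # dimensions carrying the class signal
    X_continuous: np.ndarray = field(repr=False, default=None)


def generate_synthetic_features(spec: SyntheticSpec) -> SyntheticFeatures:
    """Draw the two-class Gaussian feature matrix described by `spec`.

    Reproducible by seed; `informative_dims` may pin the signal to chosen
    columns (e.g. a single descriptor for planted-signal ablation tests).
    """
    rng = np.random.default_rng(spec.seed)
    n = 2 * spec.n_per_class
    y = np.repeat([0, 1], spec.n_per_class)
    X = rng.normal(0.0, spec.noise_sd, size=(n, spec.n_features))
    if spec.informative_dims is not None:
        dims = np.asarray(spec.informative_dims, dtype=np.int64)
    else:
        dims = rng.choice(spec.n_features, size=spec.n_informative,
                          replace=False)
    X[np.ix_(y == 1, dims)] += spec.class_separation
    Xc = X.copy()
    if spec.binarize_bits:
        nb = min(N_FINGERPRINT_BITS, spec.n_features)
        X[:, :nb] = (X[:, :nb] > 0).astype(np.float64)
    perm = rng.permutation(n)
    return SyntheticFeatures(X=X[perm], y=y[perm],
                             informative_dims=np.sort(dims),
                             X_continuous=Xc[perm])


# ---------------------------------------------------------------------------
# Synthetic SMILES tables
# ---------------------------------------------------------------------------

#: Curated pool of real, RDKit-parseable molecules.  Hazard-plausible
#: industrial chemicals/solvents/pesticides vs benign sugars, amino acids
#: and buffer components.  These labels serve fixtures only and are not a
#: toxicological claim for any individual compound.
SMILES_POOL: dict[int, list[tuple[str, str]]] = {
    1: [
        ("benzene", "c1ccccc1"),
        ("toluene", "Cc1ccccc1"),
        ("phenol", "Oc1ccccc1"),
        ("aniline", "Nc1ccccc1"),
        ("nitrobenzene", "O=[N+]([O-])c1ccccc1"),
        ("chloroform", "ClC(Cl)Cl"),
        ("carbon_tetrachloride", "ClC(Cl)(Cl)Cl"),
        ("dichloromethane", "ClCCl"),
        ("formaldehyde", "C=O"),
        ("acetonitrile", "CC#N"),
        ("acrylonitrile", "C=CC#N"),
        ("methanol", "CO"),
        ("hydrazine", "NN"),
        ("pyridine", "c1ccncc1"),
        ("epichlorohydrin", "ClCC1CO1"),
        ("acrolein", "C=CC=O"),
        ("carbon_disulfide", "S=C=S"),
        ("ethylene_oxide", "C1CO1"),
        ("naphthalene", "c1ccc2ccccc2c1"),
        ("parathion", "CCOP(=S)(OCC)Oc1ccc(cc1)[N+](=O)[O-]"),
        ("ddt", "ClC(Cl)(Cl)C(c1ccc(Cl)cc1)c1ccc(Cl)cc1"),
        ("lead_acetate", "CC(=O)O[Pb]OC(C)=O"),
        ("vinyl_chloride", "C=CCl"),
        ("allyl_alcohol", "C=CCO"),
    ],
    0: [
        ("glucose", "OC[C@H]1OC(O)[C@H](O)[C@@H](O)[C@@H]1O"),
        ("sucrose", "OC[C@H]1O[C@@](CO)(O[C@H]2O[C@H](CO)[C@@H](O)"
                    "[C@H](O)[C@H]2O)[C@@H](O)[C@@H]1O"),
        ("glycerol", "OCC(O)CO"),
        ("citric_acid", "OC(=O)CC(O)(CC(O)=O)C(O)=O"),
        ("ascorbic_acid", "OC[C@H](O)[C@H]1OC(=O)C(O)=C1O"),
        ("glycine", "NCC(O)=O"),
        ("alanine", "C[C@H](N)C(O)=O"),
        ("leucine", "CC(C)C[C@H](N)C(O)=O"),
        ("lysine", "NCCCC[C@H](N)C(O)=O"),
        ("lactic_acid", "CC(O)C(O)=O"),
        ("urea", "NC(N)=O"),
        ("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C"),
        ("sorbitol", "OC[C@H](O)[C@@H](O)[C@H](O)[C@H](O)CO"),
        ("fructose", "OCC1(O)OC[C@@H](O)[C@@H](O)[C@@H]1O"),
        ("tris_buffer", "OCC(N)(CO)CO"),
        ("hepes", "OCCN1CCN(CCS(O)(=O)=O)CC1"),
        ("nicotinamide", "NC(=O)c1cccnc1"),
        ("lumichrome_analog", "Cc1cc2nc3c(=O)[nH]c(=O)n(C)c3nc2cc1C"),
        ("xylitol", "OCC(O)C(O)C(O)CO"),
        ("succinic_acid", "OC(=O)CCC(O)=O"),
        ("gluconic_acid", "OC[C@@H](O)[C@@H](O)[C@H](O)[C@@H](O)C(O)=O"),
        ("trehalose_ring", "OC1OC(CO)C(O)C(O)C1O"),
        ("citrulline", "NC(=O)NCCC[C@H](N)C(O)=O"),
        ("myo_inositol", "OC1C(O)C(O)C(O)C(O)C1O"),
    ],
}


def generate_synthetic_smiles_table(
    n_per_class: int,
    seed: int = 0,
    replace: bool = True,
) -> list[MoleculeRecord]:
    """Sample a labeled SMILES table from the curated pool.

    With replace=False, n_per_class may not exceed the per-class pool size.
    Every emitted row is guaranteed featurizable (the pool is curated).
    """
    rng = np.random.default_rng(seed)
    records: list[MoleculeRecord] = []
    for label in (1, 0):
        pool = SMILES_POOL[label]
        if not replace and n_per_class > len(pool):
            raise ValueError(
                f"n_per_class={n_per_class} exceeds pool size {len(pool)} "
                "with replacement disabled")
        idx = rng.choice(len(pool), size=n_per_class, replace=replace)
        for i, j in enumerate(idx):
            name, smi = pool[j]
            records.append(MoleculeRecord(
                id=f"{'haz' if label else 'non'}_{i:04d}_{name}",
                smiles=smi, label=label))
    return records


def manifest_for_records(records: list[MoleculeRecord],
                         source: str = "synthetic") -> DatasetManifest:
    return DatasetManifest(
        source=source,
        n_positive=sum(1 for r in records if r.label == 1),
        n_negative=sum(1 for r in records if r.label == 0),
    )


# ---------------------------------------------------------------------------
# Logging
# ---------------------------------------------------------------------------

def setup_logging(log_path: str | Path | None = None,
                  level: int = logging.INFO) -> logging.Logger:
    """Configure package logging; optionally tee to a plain-text file."""
    root = logging.getLogger("hazchemnet")
    root.setLevel(level)
    if not any(isinstance(h, logging.StreamHandler) for h in root.handlers):
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter(
            "%(asctime)s %(name)s %(levelname)s %(message)s"))
        root.addHandler(handler)
    if log_path is not None:
        fh = logging.FileHandler(log_path)
        fh.setFormatter(logging.Formatter(
            "%(asctime)s %(name)s %(levelname)s %(message)s"))
        root.addHandler(fh)
    return root


def log_run_header(logger_: logging.Logger, cfg: TrainingConfig,
                   manifest: DatasetManifest | None = None,
                   jsonl_path: str | Path | None = None) -> dict:
    """Record seed, config hash and dataset manifest for a run."""
    from importlib.metadata import PackageNotFoundError, version
    try:
        pkg_version = version("hazchemnet")
    except PackageNotFoundError:  # pragma: no cover
        pkg_version = "unknown"
    entry = {
        "seed": cfg.seed,
        "config_hash": cfg.hash(),
        "package_version": pkg_version,
    }
    if manifest is not None:
        entry["dataset"] = {
            "source": manifest.source,
            "n_positive": manifest.n_positive,
            "n_negative": manifest.n_negative,
            "ratio": manifest.ratio,
            "checksum": manifest.checksum,
        }
    logger_.info("run header: %s", json.dumps(entry, sort_keys=True))
    if jsonl_path is not None:
        with open(jsonl_path, "a") as fh:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")
    return entry
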