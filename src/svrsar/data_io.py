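"""Dataset containers, K_i curation, and the TSV dataset dialect.

Compounds are stored as binary fingerprints (sets of on-bit indices over a
declared universe) together with a pKi potency, grouped per target into a
:class:`DataSet` that also carries the fingerprint scheme and its Tanimoto
similarity threshold ``t``.

Curation of raw K_i measurements follows standard potency-data practice:
only K_i below a cutoff (default 100 uM) are considered, multiple values for
one compound are combined when they fall within one order of magnitude
(max/min <= 10) and the compound is discarded otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParseError, ValidationError

#: Default K_i cutoff in molar units (100 uM): weaker measurements are dropped.
DEFAULT_MAX_KI = 1e-4

#: Default potency floor in pKi units applied when validating a DataSet.
DEFAULT_PKI_FLOOR = 5.0

#: Fingerprint schemes with their conventional Tc similarity thresholds:
#: 166-key MACCS uses t = 0.85, ECFP4 uses t = 0.56; synthetic data mimics
#: the higher-resolution ECFP4-like regime.
SCHEME_THRESHOLDS = {"maccs": 0.85, "ecfp4": 0.56, "synthetic": 0.56}


@dataclass(frozen=True)
class FingerprintScheme:
    """Fingerprint dialect tag plus the Tc threshold used for discontinuity."""

    name: str
    universe: int
    tc_threshold: float

    def __post_init__(self):
        if self.universe < 1:
            raise ValidationError(f"universe must be >= 1, got {self.universe}")
        if not 0.0 < self.tc_threshold <= 1.0:
            raise ValidationError(
                f"tc_threshold must be in (0, 1], got {self.tc_threshold}"
            )


@dataclass(frozen=True)
class KiRecord:
    """One raw K_i measurement (molar units) for one compound."""

    compound_id: str
    ki: float
    assay_tag: str | None = None

    def __post_init__(self):
        if not self.compound_id:
            raise ValidationError("compound_id must be non-empty")
        if not (self.ki > 0):
            raise ValidationError(f"ki must be strictly positive, got {self.ki}")


@dataclass(frozen=True)
class CompoundRecord:
    """A curated compound: fingerprint on-bits, pKi potency, optional structure."""

    compound_id: str
    fingerprint: frozenset[int]
    pki: float
    structure: str | None = None

    def __post_init__(self):
        if not self.compound_id:
            raise ValidationError("compound_id must be non-empty")
        if not self.fingerprint:
            raise ValidationError(f"{self.compound_id}: fingerprint must be non-empty")
        if not math.isfinite(self.pki):
            raise ValidationError(f"{self.compound_id}: pki must be finite")


@dataclass
class DataSet:
    """An ordered compound collection for one target, with its scheme."""

    target_id: str
    scheme: FingerprintScheme
    records: list[CompoundRecord] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self, pki_floor: float = DEFAULT_PKI_FLOOR) -> None:
        seen: set[str] = set()
        for r in self.records:
            if r.compound_id in seen:
                raise ValidationError(f"duplicate compound_id {r.compound_id!r}")
            seen.add(r.compound_id)
            if max(r.fingerprint) >= self.scheme.universe or min(r.fingerprint) < 0:
                raise ValidationError(
                    f"{r.compound_id}: on-bit index outside universe "
                    f"[0, {self.scheme.universe})"
                )
            if r.pki < pki_floor:
                raise ValidationError(
                    f"{r.compound_id}: pki {r.pki} below floor {pki_floor}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def potencies(self) -> np.ndarray:
        """pKi values in record order."""
        return np.array([r.pki for r in self.records], dtype=float)

    def fingerprint_matrix(self) -> np.ndarray:
        """Dense boolean (n, universe) on-bit matrix in record order."""
        X = np.zeros((len(self.records), self.scheme.universe), dtype=bool)
        for i, r in enumerate(self.records):
            X[i, sorted(r.fingerprint)] = True
        return X

    def with_potencies(self, pki: np.ndarray) -> "DataSet":
        """Copy of this dataset with record potencies replaced (same order)."""
        if len(pki) != len(self.records):
            raise ValidationError("potency vector length mismatch")
        recs = [replace(r, pki=float(p)) for r, p in zip(self.records, pki)]
        ds = DataSet.__new__(DataSet)  # skip floor re-validation for predicted values
        ds.target_id = self.target_id
        ds.scheme = self.scheme
        ds.records = recs
        return ds


def pki_from_ki(ki: float) -> float:
    """Convert a K_i in molar units to pKi = -log10(K_i)."""
    if not (ki > 0):
        raise ValidationError(f"ki must be strictly positive, got {ki}")
    return -math.log10(ki)


def curate_ki_records(
    records: list[KiRecord],
    max_ki: float = DEFAULT_MAX_KI,
    average: str = "pki",
) -> list[tuple[str, float]]:
    """Curate raw K_i measurements into one pKi per compound.

    Per compound: K_i values at or above ``max_ki`` are dropped first; if the
    surviving values all fall within one order of magnitude
    (max/min <= 10) they are combined into a single pKi, otherwise the
    compound is discarded entirely.

    Parameters
    ----------
    records
        Raw measurements; several records may share a compound_id.
    max_ki
        Cutoff in molar units (default 1e-4, i.e. 100 uM).
    average
        ``"pki"`` combines on the pKi scale (geometric mean of K_i, the
        default and standard potency practice); ``"ki"`` uses the arithmetic
        mean of K_i before conversion.

    Returns
    -------
    list of (compound_id, pki) in first-appearance order. Fingerprints are
    attached later. An empty result is legal.
    """
    if average not in ("pki", "ki"):
        raise ValidationError(f"average must be 'pki' or 'ki', got {average!r}")
    by_id: dict[str, list[float]] = {}
    for rec in records:
        by_id.setdefault(rec.compound_id, []).append(rec.ki)
    out: list[tuple[str, float]] = []
    for cid, kis in by_id.items():
        kept = [k for k in kis if k < max_ki]
        if not kept:
            continue
        if max(kept) / min(kept) > 10.0:
            continue  # inconsistent measurements: discard the compound
        if average == "pki":
            pki = float(np.mean([pki_from_ki(k) for k in kept]))
        else:
            pki = pki_from_ki(float(np.mean(kept)))
        out.append((cid, pki))
    return out


def _parse_fingerprint(text: str, line_number: int) -> frozenset[int]:
    try:
        bits = [int(b) for b in text.split(";") if b != ""]
    except ValueError as exc:
        raise ParseError(f"bad fingerprint field {text!r}", line_number) from exc
    if not bits:
        raise ParseError("empty fingerprint", line_number)
    return frozenset(bits)


def read_dataset(path, pki_floor: float = DEFAULT_PKI_FLOOR) -> DataSet:
    """Read a dataset from the TSV dialect written by :func:`write_dataset`.

    The dialect is UTF-8 TSV with ``#key=value`` metadata lines
    (``target_id``, ``scheme``, ``universe``, ``tc_threshold``) before a
    header row ``compound_id  pki  fingerprint  [smiles]``; fingerprints are
    semicolon-separated ascending on-bit indices.
    """
    meta: dict[str, str] = {}
    header: list[str] | None = None
    records: list[CompoundRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if header is not None:
                    raise ParseError("metadata line after header", lineno)
                if "=" not in line:
                    raise ParseError(f"malformed metadata line {line!r}", lineno)
                key, _, value = line[1:].partition("=")
                meta[key.strip()] = value.strip()
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if header[:3] != ["compound_id", "pki", "fingerprint"]:
                    raise ParseError(f"unexpected header {header!r}", lineno)
                continue
            if len(fields) < 3:
                raise ParseError(f"expected >= 3 fields, got {len(fields)}", lineno)
            try:
                pki = float(fields[1])
            except ValueError as exc:
                raise ParseError(f"bad pki field {fields[1]!r}", lineno) from exc
            fp = _parse_fingerprint(fields[2], lineno)
            smiles = fields[3] if len(fields) > 3 and fields[3] else None
            records.append(CompoundRecord(fields[0], fp, pki, smiles))
    if header is None:
        raise ParseError("no header row found")
    for key in ("target_id", "scheme", "universe", "tc_threshold"):
        if key not in meta:
            raise ParseError(f"missing #{key}= metadata line")
    scheme = FingerprintScheme(
        meta["scheme"], int(meta["universe"]), float(meta["tc_threshold"])
    )
    ds = DataSet.__new__(DataSet)
    ds.target_id = meta["target_id"]
    ds.scheme = scheme
    ds.records = records
    ds.validate(pki_floor=pki_floor)
    return ds


def write_dataset(dataset: DataSet, path) -> None:
    """Write a dataset in the canonical TSV dialect (round-trip exact)."""
    has_smiles = any(r.structure for r in dataset.records)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"#target_id={dataset.target_id}\n")
        fh.write(f"#scheme={dataset.scheme.name}\n")
        fh.write(f"#universe={dataset.scheme.universe}\n")
        fh.write(f"#tc_threshold={dataset.scheme.tc_threshold!r}\n")
        cols = ["compound_id", "pki", "fingerprint"] + (["smiles"] if has_smiles else [])
        fh.write("\t".join(cols) + "\n")
        for r in dataset.records:
            fp = ";".join(str(b) for b in sorted(r.fingerprint))
            row = [r.compound_id, repr(r.pki), fp]
            if has_smiles:
                row.append(r.structure or "")
            fh.write("\t".join(row) + "\n")


def dataset_summary(dataset: DataSet) -> dict[str, float]:
    """n, min/max/mean pKi — the per-target overview statistics."""
    if len(dataset) == 0:
        raise ValidationError("dataset_summary requires a non-empty dataset")
    p = dataset.potencies()
    return {
        "n": len(p),
        "min_pki": float(p.min()),
        "max_pki": float(p.max()),
        "mean_pki": float(p.mean()),
    }


def fingerprints_from_smiles(smiles: list[str], scheme: str = "ecfp4"):
    """Optional adapter: featurize SMILES with RDKit (imported lazily).

    Returns a list of frozensets of on-bit indices; scheme 'maccs' (universe
    167) or 'ecfp4' (Morgan radius 2 folded to 1024 bits).
    """
    from rdkit import Chem  # noqa: deferred heavy import
    from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

    out = []
    if scheme == "ecfp4":
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=1024)
    elif scheme != "maccs":
        raise ValidationError(f"unknown scheme {scheme!r}")
    for smi in smiles:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValidationError(f"unparseable SMILES {smi!r}")
        if scheme == "maccs":
            fp = MACCSkeys.GenMACCSKeys(mol)
            out.append(frozenset(fp.GetOnBits()))
        else:
            out.append(frozenset(gen.GetFingerprint(mol).GetOnBits()))
    return out
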