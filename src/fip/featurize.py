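"""Compound ingestion, standardization, deduplication and fingerprint encoding.

The chemistry path runs entirely on RDKit: SMILES/SDF parsing, a declared
standardization contract (stereo removal, largest organic fragment,
charge neutralization), InChIKey-based deduplication and binary
fingerprint generation (MACCS structure keys, folded Morgan/ECFP).
881-bit PubChem-style keys are accepted as pre-encoded input (FPS) but
cannot be generated here; see :func:`encode`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

import numpy as np
import rdkit
from rdkit import Chem, RDLogger
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

#: Semantic bit counts of the dictionary-based structure keys. RDKit's raw
#: MACCS array carries a placeholder bit 0; only the 166 semantic bits are
#: ever exposed, so matrix dimensions are 166 regardless of storage padding.
MACCS_BITS = 166
PUBCHEMKEY_BITS = 881
DEFAULT_ECFP_BITS = 1024

TOOLKIT = f"rdkit/{rdkit.__version__}"

FINGERPRINT_KINDS = ("maccs", "pubchemkey", "ecfp")


class FeaturizeError(ValueError):
    pass


class UnsupportedFingerprintError(FeaturizeError):
    pass


@dataclass(frozen=True)
class FingerprintSpec:
    """Which binary fingerprint encodes compounds, and at what length.

    kind : "maccs" (166-bit structure key), "pubchemkey" (881-bit structure
        key, pre-encoded input only) or "ecfp" (folded circular fingerprint;
        radius 2 = ECFP4, radius 3 = ECFP6).
    """

    kind: str
    length: int
    radius: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in FINGERPRINT_KINDS:
            raise FeaturizeError(f"unknown fingerprint kind {self.kind!r}")
        if self.length <= 0:
            raise FeaturizeError("fingerprint length must be positive")
        if (self.radius is not None) != (self.kind == "ecfp"):
            raise FeaturizeError("radius is required for ecfp and forbidden otherwise")

    @classmethod
    def maccs(cls) -> "FingerprintSpec":
        return cls("maccs", MACCS_BITS)

    @classmethod
    def pubchemkey(cls) -> "FingerprintSpec":
        return cls("pubchemkey", PUBCHEMKEY_BITS)

    @classmethod
    def ecfp(cls, radius: int = 2, length: int = DEFAULT_ECFP_BITS) -> "FingerprintSpec":
        return cls("ecfp", length, radius)

    def label(self) -> str:
        if self.kind == "ecfp":
            return f"ecfp/{self.length}/radius={self.radius}"
        return f"{self.kind}/{self.length}"

    @classmethod
    def from_label(cls, label: str) -> "FingerprintSpec":
        parts = label.split("/")
        if parts[0] == "ecfp":
            return cls("ecfp", int(parts[1]), int(parts[2].split("=")[1]))
        return cls(parts[0], int(parts[1]))


@dataclass
class CompoundRecord:
    """One compound: a SMILES line, its identifier, and (after
    standardization) the InChIKey used for deduplication."""

    smiles: str
    id: str
    inchikey: Optional[str] = None


@dataclass
class FeatureVector:
    """Fixed-length binary feature vector of one compound."""

    bits: np.ndarray
    spec: FingerprintSpec
    compound_id: str

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 1 or self.bits.size != self.spec.length:
            raise FeaturizeError(
                f"feature vector length {self.bits.size} != spec length {self.spec.length}"
            )
        if not np.all((self.bits == 0) | (self.bits == 1)):
            raise FeaturizeError("feature vector elements must be 0 or 1")

    def popcount(self) -> int:
        return int(self.bits.sum())


@dataclass
class RejectLog:
    """Collects (compound id, reason) for every record that fails parsing,
    standardization or encoding; nothing is dropped silently."""

    entries: list = field(default_factory=list)

    def add(self, compound_id: str, reason: str) -> None:
        self.entries.append((compound_id, reason))

    def __len__(self) -> int:
        return len(self.entries)

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("compound_id\treason\n")
            for cid, reason in self.entries:
                fh.write(f"{cid}\t{reason}\n")


def read_compounds(
    path: str, format: str = "smi", rejects: Optional[RejectLog] = None
) -> Iterator[CompoundRecord]:
    """Stream compound records from a .smi ("SMILES<ws>ID" per line) or SDF file.

    Unparsable entries go to `rejects`; a file yielding zero parsable
    records raises FeaturizeError once the stream is exhausted.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format not in ("smi", "sdf"):
        raise FeaturizeError(f"unknown format {format!r}")
    rejects = rejects if rejects is not None else RejectLog()

    def _gen() -> Iterator[CompoundRecord]:
        n_ok = 0
        if format == "smi":
            with open(path) as fh:
                for lineno, line in enumerate(fh, 1):
                    line = line.strip()
                    if not line:
                        continue
                    parts = line.split(None, 1)
                    smiles = parts[0]
                    cid = parts[1].strip() if len(parts) > 1 else f"line{lineno}"
                    if Chem.MolFromSmiles(smiles) is None:
                        rejects.add(cid, f"unparsable SMILES: {smiles}")
                        continue
                    n_ok += 1
                    yield CompoundRecord(smiles=smiles, id=cid)
        else:
            supplier = Chem.SDMolSupplier(path, sanitize=True)
            for idx, mol in enumerate(supplier):
                if mol is None:
                    rejects.add(f"sdf_record_{idx}", "unparsable SDF record")
                    continue
                cid = mol.GetProp("_Name") if mol.HasProp("_Name") else f"sdf_record_{idx}"
                n_ok += 1
                yield CompoundRecord(smiles=Chem.MolToSmiles(mol), id=cid or f"sdf_record_{idx}")
        if n_ok == 0:
            raise FeaturizeError(f"no parsable records in {path}")

    return _gen()


_LARGEST_FRAGMENT = rdMolStandardize.LargestFragmentChooser(preferOrganic=True)
_UNCHARGER = rdMolStandardize.Uncharger()


def _standardize_mol(mol: Chem.Mol) -> Chem.Mol:
    mol = rdMolStandardize.Cleanup(mol)
    mol = _LARGEST_FRAGMENT.choose(mol)
    mol = _UNCHARGER.uncharge(mol)
    Chem.RemoveStereochemistry(mol)  # tetrahedral and double-bond descriptors
    Chem.SanitizeMol(mol)
    return mol


def standardize(
    record: CompoundRecord, rejects: Optional[RejectLog] = None
) -> Optional[CompoundRecord]:
    """Apply the standardization contract and recompute the InChIKey.

    Contract: strip all stereochemistry, keep the largest organic fragment
    (desalting), neutralize charges where valence permits; no tautomer
    canonicalization. Idempotent. Failures are routed to `rejects` and
    return None.
    """
    try:
        mol = Chem.MolFromSmiles(record.smiles)
        if mol is None:
            raise FeaturizeError("unparsable SMILES")
        mol = _standardize_mol(mol)
        inchikey = Chem.MolToInchiKey(mol)
        if not inchikey:
            raise FeaturizeError("empty InChIKey")
    except Exception as exc:  # rdkit raises a zoo of exception types
        if rejects is not None:
            rejects.add(record.id, f"standardization failed: {exc}")
            return None
        raise FeaturizeError(f"standardization failed for {record.id}: {exc}") from exc
    return replace(record, smiles=Chem.MolToSmiles(mol), inchikey=inchikey)


@dataclass
class DedupStats:
    n_seen: int = 0
    n_unique: int = 0

    @property
    def n_duplicates(self) -> int:
        return self.n_seen - self.n_unique


def deduplicate(
    records: Iterable[CompoundRecord], stats: Optional[DedupStats] = None
) -> Iterator[CompoundRecord]:
    """Keep the first occurrence of each InChIKey; count duplicates in `stats`."""
    seen: set = set()
    for rec in records:
        if rec.inchikey is None:
            raise FeaturizeError(f"record {rec.id} not standardized (no InChIKey)")
        if stats is not None:
            stats.n_seen += 1
        if rec.inchikey in seen:
            continue
        seen.add(rec.inchikey)
        if stats is not None:
            stats.n_unique += 1
        yield rec


def encode(
    record: CompoundRecord, spec: FingerprintSpec, rejects: Optional[RejectLog] = None
) -> Optional[FeatureVector]:
    """Encode a standardized compound into a binary feature vector.

    maccs drops RDKit's placeholder bit 0 so indices 0..165 are the 166
    semantic keys; ecfp uses the Morgan generator folded to spec.length.
    """
    if spec.kind == "pubchemkey":
        raise UnsupportedFingerprintError(
            "no encoder for 881-bit PubChem-style keys is available; "
            "supply pre-encoded fingerprints in FPS format instead"
        )
    try:
        mol = Chem.MolFromSmiles(record.smiles)
        if mol is None:
            raise FeaturizeError("unparsable SMILES")
        if spec.kind == "maccs":
            raw = MACCSkeys.GenMACCSKeys(mol)  # 167 bits, bit 0 unused
            bits = np.zeros(167, dtype=np.uint8)
            bits[list(raw.GetOnBits())] = 1
            bits = bits[1:]
            if spec.length != MACCS_BITS:
                raise FeaturizeError("maccs spec length must be 166")
        else:  # ecfp
            gen = rdFingerprintGenerator.GetMorganGenerator(
                radius=spec.radius, fpSize=spec.length
            )
            fp = gen.GetFingerprint(mol)
            bits = np.zeros(spec.length, dtype=np.uint8)
            bits[list(fp.GetOnBits())] = 1
    except UnsupportedFingerprintError:
        raise
    except Exception as exc:
        if rejects is not None:
            rejects.add(record.id, f"encoding failed: {exc}")
            return None
        raise FeaturizeError(f"encoding failed for {record.id}: {exc}") from exc
    return FeatureVector(bits=bits, spec=spec, compound_id=record.id)


# ---------------------------------------------------------------------------
# FPS interchange format (chemfp dialect): '#' header lines, then one
# "<hex fingerprint>\t<id>" record per line. Bit i lives in byte i // 8 at
# in-byte position i % 8 (LSB first), i.e. numpy packbits(bitorder="little").
# ---------------------------------------------------------------------------


def write_fps(
    vectors: Iterable[FeatureVector], path: str, software: str = f"fip {TOOLKIT}"
) -> int:
    """Write feature vectors to an FPS file; returns the record count.

    All vectors must share one FingerprintSpec; the spec, bit count and
    toolkit version go into the header so readers can refuse mismatches.
    """
    vectors = list(vectors)
    spec: Optional[FingerprintSpec] = vectors[0].spec if vectors else None
    with open(path, "w") as fh:
        fh.write("#FPS1\n")
        if spec is not None:
            fh.write(f"#num_bits={spec.length}\n")
            fh.write(f"#type={spec.label()}\n")
        fh.write(f"#software={software}\n")
        for vec in vectors:
            if vec.spec != spec:
                raise FeaturizeError("mixed fingerprint specs in one FPS file")
            hexfp = np.packbits(vec.bits, bitorder="little").tobytes().hex()
            fh.write(f"{hexfp}\t{vec.compound_id}\n")
    return len(vectors)


def read_fps(path: str) -> list[FeatureVector]:
    """Read an FPS file back into feature vectors (bit-exact round trip)."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    num_bits: Optional[int] = None
    spec: Optional[FingerprintSpec] = None
    saw_header = False
    vectors: list[FeatureVector] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                saw_header = True
                if line.startswith("#num_bits="):
                    num_bits = int(line.split("=", 1)[1])
                elif line.startswith("#type="):
                    spec = FingerprintSpec.from_label(line.split("=", 1)[1])
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FeaturizeError(f"malformed FPS record: {line!r}")
            hexfp, cid = parts[0], parts[1]
            if num_bits is None:
                raise FeaturizeError("FPS file lacks a #num_bits header")
            nbytes = (num_bits + 7) // 8
            if len(hexfp) != 2 * nbytes:
                raise FeaturizeError(
                    f"record length {len(hexfp) // 2} bytes does not match "
                    f"declared num_bits={num_bits}"
                )
            if spec is None:
                spec = FingerprintSpec("ecfp", num_bits, 2) if num_bits not in (
                    MACCS_BITS,
                    PUBCHEMKEY_BITS,
                ) else (
                    FingerprintSpec.maccs()
                    if num_bits == MACCS_BITS
                    else FingerprintSpec.pubchemkey()
                )
            if spec.length != num_bits:
                raise FeaturizeError("#type and #num_bits headers disagree")
            bits = np.unpackbits(
                np.frombuffer(bytes.fromhex(hexfp), dtype=np.uint8),
                bitorder="little",
            )[:num_bits]
            vectors.append(FeatureVector(bits=bits, spec=spec, compound_id=cid))
    if num_bits is None and not saw_header:
        raise FeaturizeError(f"{path} is not an FPS file (no header)")
    return vectors


def stack_vectors(vectors: Iterable[FeatureVector]) -> tuple[np.ndarray, FingerprintSpec, list]:
    """Stack a stream of vectors into an (n, D) uint8 matrix.

    Raises on an empty stream or mixed specs — every matrix accumulator
    funnels through here.
    """
    vecs = list(vectors)
    if not vecs:
        raise FeaturizeError("empty feature vector stream")
    spec = vecs[0].spec
    for v in vecs:
        if v.spec != spec:
            raise FeaturizeError(f"mixed fingerprint specs: {v.spec} vs {spec}")
    mat = np.stack([v.bits for v in vecs]).astype(np.uint8)
    ids = [v.compound_id for v in vecs]
    return mat, spec, ids


def vectors_from_matrix(
    mat: np.ndarray, spec: FingerprintSpec, ids: Optional[list] = None
) -> list[FeatureVector]:
    """Wrap the rows of a binary (n, D) matrix as FeatureVectors."""
    mat = np.asarray(mat, dtype=np.uint8)
    if ids is None:
        ids = [f"c{i}" for i in range(mat.shape[0])]
    return [
        FeatureVector(bits=row, spec=spec, compound_id=cid)
        for row, cid in zip(mat, ids)
    ]
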