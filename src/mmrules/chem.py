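"""Metabolite structures, molecular fingerprints and chemical distances.

Metabolites arrive as database identifiers (HMDB, KEGG, PubChem CID,
InChI, InChIKey).  InChI (and SMILES) carry the structure directly; the
database identifiers are resolved through a local JSON cache, optionally
populated from the PubChem PUG REST service when a network is available.
Unresolved metabolites are excluded from distance computation with a
warning rather than failing the run.

Five fingerprints are supported:

* ``cactvs`` -- the 881-bit PubChem substructure fingerprint.  These bits
  are distributed with PubChem compound records (base64-encoded, 4-byte
  big-endian bit-count prefix); they are decoded from the cache, never
  recomputed locally.
* ``morgan`` -- 2048-bit extended-connectivity fingerprint (radius 2),
  computed with RDKit.
* ``mqn`` -- the 42 Molecular Quantum Number counts, computed with RDKit.
* ``map4`` / ``infomax`` -- optional backends; raise
  :class:`FingerprintBackendUnavailable` when their software is absent.

Binary fingerprints are compared with the Tanimoto/Jaccard distance, MQN
with the city-block (L1) distance.
"""

from __future__ import annotations

import base64
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import DistanceMatrix

__all__ = [
    "MetaboliteID",
    "Fingerprint",
    "FingerprintBackendUnavailable",
    "StructureCache",
    "resolve_structure",
    "decode_cactvs",
    "fingerprint",
    "tanimoto_distance",
    "cityblock_distance",
    "build_metabolite_distances",
    "read_metabolite_ids",
    "read_distance_table",
    "FINGERPRINT_LENGTHS",
]

ID_TYPES = ("HMDB", "KEGG", "InChI", "InChIKey", "PubChemCID", "SMILES")

FINGERPRINT_LENGTHS = {
    "cactvs": 881,
    "morgan": 2048,
    "mqn": 42,
    "map4": 1024,
    "infomax": 300,
}

BINARY_METHODS = ("cactvs", "morgan")


class FingerprintBackendUnavailable(RuntimeError):
    """An optional fingerprint backend is not installed."""


@dataclass
class MetaboliteID:
    """A metabolite identifier with its (possibly resolved) structure."""

    feature_id: str
    id_type: str
    value: str
    resolved_structure: str | None = None  # canonical SMILES
    cactvs_bits: np.ndarray | None = None  # decoded 881-bit vector, if cached
    unresolved_reason: str | None = None

    def __post_init__(self) -> None:
        if self.id_type not in ID_TYPES:
            raise ValueError(f"unknown id_type {self.id_type!r}")
        if not self.value:
            raise ValueError("empty identifier value")

    @property
    def resolved(self) -> bool:
        return self.resolved_structure is not None or self.cactvs_bits is not None


@dataclass
class Fingerprint:
    """A molecular fingerprint vector with its method tag."""

    method: str
    vector: np.ndarray
    is_binary: bool

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector)
        want = FINGERPRINT_LENGTHS[self.method]
        if self.vector.shape != (want,):
            raise ValueError(
                f"{self.method} fingerprint must have length {want}, got {self.vector.shape}"
            )
        if self.is_binary and not set(np.unique(self.vector)) <= {0, 1}:
            raise ValueError("binary fingerprint contains values outside {0,1}")


class StructureCache:
    """A JSON-backed cache mapping '<TYPE>:<value>' to structure records.

    Records are dicts that may contain ``smiles`` and/or ``cactvs_b64``
    (the base64-encoded PubChem fingerprint field).
    """

    def __init__(self, path: str | Path | None = None):
        self.path = None if path is None else Path(path)
        self._data: dict[str, dict] = {}
        if self.path is not None and self.path.exists():
            self._data = json.loads(self.path.read_text())

    def get(self, key: str) -> dict | None:
        return self._data.get(key)

    def put(self, key: str, record: dict) -> None:
        self._data[key] = record
        if self.path is not None:
            self.path.write_text(json.dumps(self._data, indent=1, sort_keys=True))


def decode_cactvs(b64: str) -> np.ndarray:
    """Decode PubChem's base64 fingerprint field into an 881-bit 0/1 vector.

    The field is base64 over a 4-byte big-endian bit count (881) followed
    by the packed bits, most-significant bit first.
    """
    raw = base64.b64decode(b64)
    if len(raw) < 5:
        raise ValueError("CACTVS field too short")
    nbits = int.from_bytes(raw[:4], "big")
    payload = raw[4:] if nbits == 881 else raw
    bits = np.unpackbits(np.frombuffer(payload, dtype=np.uint8))
    if bits.size < 881:
        raise ValueError(f"CACTVS field has only {bits.size} bits")
    return bits[:881].astype(np.int8)


def encode_cactvs(bits: np.ndarray) -> str:
    """Inverse of :func:`decode_cactvs` (used to build cache records)."""
    bits = np.asarray(bits, dtype=np.uint8)
    if bits.shape != (881,):
        raise ValueError("expected 881 bits")
    packed = np.packbits(bits)
    return base64.b64encode((881).to_bytes(4, "big") + packed.tobytes()).decode()


def _pubchem_lookup(id_type: str, value: str) -> dict | None:
    """Best-effort online PubChem lookup; returns None on any failure."""
    import urllib.request

    ns = {
        "PubChemCID": f"compound/cid/{value}",
        "InChIKey": f"compound/inchikey/{value}",
        "HMDB": f"compound/xref/RegistryID/{value}",
        "KEGG": f"compound/xref/RegistryID/{value}",
    }.get(id_type)
    if ns is None:
        return None
    url = (
        "https://pubchem.ncbi.nlm.nih.gov/rest/pug/"
        f"{ns}/property/CanonicalSMILES,Fingerprint2D/JSON"
    )
    try:
        with urllib.request.urlopen(url, timeout=10) as resp:
            props = json.loads(resp.read())["PropertyTable"]["Properties"][0]
        return {
            "smiles": props.get("CanonicalSMILES"),
            "cactvs_b64": props.get("Fingerprint2D"),
        }
    except Exception:  # noqa: BLE001 - network errors flag as unresolved
        return None


def _canonical_smiles(structure: str) -> str | None:
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.*")
    mol = (
        Chem.MolFromInchi(structure)
        if structure.startswith("InChI=")
        else Chem.MolFromSmiles(structure)
    )
    return None if mol is None else Chem.MolToSmiles(mol)


def resolve_structure(
    mid: MetaboliteID,
    cache: StructureCache | None = None,
    *,
    allow_network: bool = False,
) -> MetaboliteID:
    """Fill ``resolved_structure`` (and cached CACTVS bits) for one metabolite.

    InChI and SMILES identifiers resolve locally.  Database identifiers
    are looked up in ``cache``; on a cache miss, a PubChem lookup is
    attempted only when ``allow_network`` is set.  Failures flag the
    metabolite unresolved rather than raising.
    """
    if mid.resolved:
        return mid
    if mid.id_type in ("InChI", "SMILES"):
        smiles = _canonical_smiles(mid.value)
        if smiles is None:
            mid.unresolved_reason = "unparsable structure"
        else:
            mid.resolved_structure = smiles
        return mid
    key = f"{mid.id_type}:{mid.value}"
    record = cache.get(key) if cache is not None else None
    if record is None and allow_network:
        record = _pubchem_lookup(mid.id_type, mid.value)
        if record is not None and cache is not None:
            cache.put(key, record)
    if record is None:
        mid.unresolved_reason = "not in cache and no network lookup"
        return mid
    if record.get("smiles"):
        mid.resolved_structure = _canonical_smiles(record["smiles"])
    if record.get("cactvs_b64"):
        mid.cactvs_bits = decode_cactvs(record["cactvs_b64"])
    if not mid.resolved:
        mid.unresolved_reason = "cache record has no usable structure"
    return mid


def fingerprint(structure: str, method: str = "morgan") -> Fingerprint:
    """Compute a fingerprint from a SMILES or InChI structure string."""
    if method not in FINGERPRINT_LENGTHS:
        raise ValueError(f"unknown fingerprint method {method!r}")
    if not structure:
        raise ValueError("empty structure string")
    if method == "cactvs":
        raise ValueError(
            "CACTVS fingerprints are decoded from PubChem records, not computed; "
            "resolve the metabolite through the cache instead"
        )
    if method in ("map4", "infomax"):
        raise FingerprintBackendUnavailable(
            f"the {method!r} fingerprint requires its optional backend "
            f"({'map4' if method == 'map4' else 'dgllife'}), which is not installed"
        )
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator, rdMolDescriptors
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.*")
    mol = (
        Chem.MolFromInchi(structure)
        if structure.startswith("InChI=")
        else Chem.MolFromSmiles(structure)
    )
    if mol is None:
        raise ValueError(f"unparsable structure: {structure!r}")
    if method == "morgan":
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
        arr = np.array(gen.GetFingerprint(mol), dtype=np.int8)
        return Fingerprint("morgan", arr, is_binary=True)
    # mqn
    counts = np.array(rdMolDescriptors.MQNs_(mol), dtype=float)
    return Fingerprint("mqn", counts, is_binary=False)


def tanimoto_distance(a: Fingerprint, b: Fingerprint) -> float:
    """1 - |a AND b| / |a OR b| for binary fingerprints of one method.

    Two all-zero vectors are at distance 0; all-zero vs nonzero is 1.
    """
    if a.method != b.method:
        raise ValueError(f"method mismatch: {a.method} vs {b.method}")
    if not (a.is_binary and b.is_binary):
        raise ValueError("tanimoto_distance requires binary fingerprints")
    av, bv = a.vector.astype(bool), b.vector.astype(bool)
    union = np.sum(av | bv)
    if union == 0:
        return 0.0
    return 1.0 - np.sum(av & bv) / union


def cityblock_distance(a: Fingerprint, b: Fingerprint) -> float:
    """L1 distance between MQN count vectors."""
    if a.method != b.method:
        raise ValueError(f"method mismatch: {a.method} vs {b.method}")
    if a.method != "mqn":
        raise ValueError("cityblock_distance is defined for MQN fingerprints")
    return float(np.abs(a.vector.astype(float) - b.vector.astype(float)).sum())


def build_metabolite_distances(
    ids: list[MetaboliteID],
    method: str = "cactvs",
    cache: StructureCache | None = None,
    *,
    allow_network: bool = False,
) -> tuple[DistanceMatrix, list[MetaboliteID]]:
    """Pairwise metabolite distances over all resolvable metabolites.

    Returns the distance matrix (labelled by feature id) and the list of
    metabolites that could not be resolved (excluded with a warning).
    """
    resolved: list[tuple[str, Fingerprint]] = []
    unresolved: list[MetaboliteID] = []
    for mid in ids:
        mid = resolve_structure(mid, cache, allow_network=allow_network)
        fp: Fingerprint | None = None
        if method == "cactvs":
            if mid.cactvs_bits is not None:
                fp = Fingerprint("cactvs", mid.cactvs_bits.astype(np.int8), is_binary=True)
        elif mid.resolved_structure is not None:
            try:
                fp = fingerprint(mid.resolved_structure, method)
            except ValueError:
                fp = None
        if fp is None:
            if mid.unresolved_reason is None:
                mid.unresolved_reason = f"no {method} fingerprint available"
            unresolved.append(mid)
        else:
            resolved.append((mid.feature_id, fp))
    if unresolved:
        warnings.warn(
            f"excluding {len(unresolved)} unresolved metabolite(s): "
            f"{[m.feature_id for m in unresolved]}"
        )
    if len(resolved) < 2:
        raise ValueError("fewer than 2 metabolites could be resolved")
    labels = [fid for fid, _ in resolved]
    n = len(resolved)
    D = np.zeros((n, n))
    metric = tanimoto_distance if method in BINARY_METHODS else cityblock_distance
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = metric(resolved[i][1], resolved[j][1])
    return DistanceMatrix(D, labels), unresolved


def read_metabolite_ids(path: str, sep: str | None = None) -> list[MetaboliteID]:
    """Read a (feature_id, id_type, id_value) CSV/TSV into MetaboliteIDs."""
    sep = sep if sep is not None else ("\t" if str(path).endswith((".tsv", ".txt")) else ",")
    df = pd.read_csv(path, sep=sep, dtype=str)
    need = {"feature_id", "id_type", "id_value"}
    if not need <= set(df.columns):
        raise ValueError(f"metabolite ID table must have columns {sorted(need)}")
    return [
        MetaboliteID(str(r.feature_id), str(r.id_type), str(r.id_value))
        for r in df.itertuples()
    ]


def read_distance_table(
    path: str, *, similarities: bool = False, sep: str | None = None
) -> DistanceMatrix:
    """Read a precomputed square distance (or similarity) table.

    With ``similarities=True`` values are converted via d = 1 - s, clipped
    to [0, 1].
    """
    sep = sep if sep is not None else ("\t" if str(path).endswith((".tsv", ".txt")) else ",")
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    vals = df.to_numpy(dtype=float)
    if similarities:
        vals = np.clip(1.0 - vals, 0.0, 1.0)
        np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(vals, [str(c) for c in df.columns])
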