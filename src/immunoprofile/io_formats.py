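"""Readers and writers for all external representations.

Structures are exchanged as single-chain PDB files (parsed with gemmi);
everything else is flat TSV/JSON with schemas documented on the reader
functions.  All residue coordinates are 1-based inclusive throughout the
package (UniProt convention).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import gemmi
import numpy as np
import pandas as pd

from .constants import AMINO_ACIDS, ONE_TO_THREE, THREE_TO_ONE

logger = logging.getLogger(__name__)

OUTCOME_VOCABULARY = ("uncertain", "approved", "supported", "enhanced", "untested")
PTM_CATEGORIES = ("modified_residue", "glycosylation", "lipidation")
BACKBONE_ATOMS = ("N", "CA", "C")


class FormatError(ValueError):
    """A file violated its documented schema; message locates the offence."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Residue:
    """One residue of a parsed chain: 1-based index, 1-letter code, atoms."""

    index: int
    amino_acid: str
    atom_names: list[str]
    coords: np.ndarray  # (n_atoms, 3) in Angstrom

    @property
    def incomplete(self) -> bool:
        return any(a not in self.atom_names for a in BACKBONE_ATOMS)

    def atom(self, name: str) -> np.ndarray | None:
        try:
            return self.coords[self.atom_names.index(name)]
        except ValueError:
            return None


@dataclass
class ProteinStructure:
    """Single-chain heavy-atom structure; substrate for all geometric features."""

    protein_id: str
    residues: list[Residue]

    def __post_init__(self) -> None:
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError(f"{self.protein_id}: residue indices not strictly increasing")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.amino_acid for r in self.residues)

    def all_atoms(self) -> tuple[np.ndarray, np.ndarray]:
        """(coords stacked over residues, residue position index per atom)."""
        coords = np.concatenate([r.coords for r in self.residues])
        owner = np.concatenate(
            [np.full(len(r.atom_names), i) for i, r in enumerate(self.residues)]
        )
        return coords, owner


@dataclass
class ProteinAnnotations:
    """UniProt-style per-protein features, 1-based inclusive coordinates."""

    protein_id: str
    sequence: str
    tm_ranges: list[tuple[int, int]] = field(default_factory=list)
    disulfide_pairs: list[tuple[int, int]] = field(default_factory=list)
    ptm_sites: dict[int, str] = field(default_factory=dict)
    localization_label: str | None = None

    def __post_init__(self) -> None:
        length = len(self.sequence)
        bad = [s for s in self.sequence if s not in AMINO_ACIDS]
        if bad:
            raise FormatError(
                f"{self.protein_id}: non-standard residue letters {sorted(set(bad))}"
            )
        for s, e in self.tm_ranges:
            if not (1 <= s <= e <= length):
                raise FormatError(f"{self.protein_id}: TM range {s}..{e} outside 1..{length}")
        for i, j in self.disulfide_pairs:
            for k in (i, j):
                if not 1 <= k <= length:
                    raise FormatError(f"{self.protein_id}: disulfide index {k} outside sequence")
                if self.sequence[k - 1] != "C":
                    raise FormatError(
                        f"{self.protein_id}: disulfide position {k} is "
                        f"{self.sequence[k - 1]}, not cysteine"
                    )
        for k, cat in self.ptm_sites.items():
            if not 1 <= k <= length:
                raise FormatError(f"{self.protein_id}: PTM site {k} outside sequence")
            if cat not in PTM_CATEGORIES:
                raise FormatError(f"{self.protein_id}: unknown PTM category {cat!r}")


@dataclass
class DisorderTrack:
    """Per-residue predicted disorder scores in [0, 1] for one protein."""

    protein_id: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1:
            raise FormatError(f"{self.protein_id}: disorder track must be 1-D")
        if np.any((self.scores < 0) | (self.scores > 1)):
            raise FormatError(f"{self.protein_id}: disorder scores outside [0, 1]")


@dataclass
class AntibodyRecord:
    """One antibody with its immunogen and per-technology validation outcomes."""

    antibody_id: str
    protein_id: str
    immunogen_sequence: str
    outcome_wb: str
    outcome_ihc: str
    outcome_icc: str
    wb_bands: list[float] | None = None  # kDa; None iff outcome_wb == "untested"

    def __post_init__(self) -> None:
        if not self.immunogen_sequence:
            raise FormatError(f"{self.antibody_id}: empty immunogen sequence")
        bad = [c for c in self.immunogen_sequence if c not in AMINO_ACIDS]
        if bad:
            raise FormatError(
                f"{self.antibody_id}: non-standard immunogen letters {sorted(set(bad))}"
            )
        for tech, outcome in (("wb", self.outcome_wb), ("ihc", self.outcome_ihc),
                              ("icc", self.outcome_icc)):
            if outcome not in OUTCOME_VOCABULARY:
                raise FormatError(
                    f"{self.antibody_id}: outcome_{tech}={outcome!r} not in "
                    f"{OUTCOME_VOCABULARY}"
                )
        if self.outcome_wb == "untested":
            if self.wb_bands:
                raise FormatError(f"{self.antibody_id}: WB bands present but WB untested")
            self.wb_bands = None
        elif self.wb_bands is None:
            self.wb_bands = []
        if self.wb_bands and any(b < 0 for b in self.wb_bands):
            raise FormatError(f"{self.antibody_id}: negative WB band size")


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

def read_structure(path: str | Path) -> ProteinStructure:
    """Read the first chain of a single-model PDB file.

    HETATM records (waters, ligands) are dropped.  Residues missing any of
    the N/CA/C backbone atoms are kept but flagged incomplete (a warning is
    logged).  A multi-chain file triggers a warning and only the first chain
    is read.
    """
    path = Path(path)
    st = gemmi.read_pdb(str(path))
    if len(st) == 0 or len(st[0]) == 0:
        raise FormatError(f"{path}: no model/chain found")
    if len(st) > 1:
        warnings.warn(f"{path}: {len(st)} models; reading the first", stacklevel=2)
    model = st[0]
    if len(model) > 1:
        warnings.warn(f"{path}: {len(model)} chains; reading the first", stacklevel=2)
    chain = model[0]
    residues: list[Residue] = []
    for res in chain:
        if res.het_flag != "A":  # drop HETATM incl. waters
            continue
        aa = THREE_TO_ONE.get(res.name)
        if aa is None:
            raise FormatError(f"{path}: non-standard residue {res.name} at {res.seqid.num}")
        names = [a.name for a in res]
        coords = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in res], dtype=float)
        r = Residue(index=res.seqid.num, amino_acid=aa, atom_names=names, coords=coords)
        if r.incomplete:
            logger.warning("%s: residue %d missing backbone atoms", path, r.index)
        residues.append(r)
    return ProteinStructure(protein_id=path.stem, residues=residues)


def write_structure(structure: ProteinStructure, path: str | Path) -> None:
    """Write a ProteinStructure as a minimal single-chain PDB file."""
    lines = []
    serial = 1
    for res in structure.residues:
        res3 = ONE_TO_THREE[res.amino_acid]
        for name, (x, y, z) in zip(res.atom_names, res.coords):
            lines.append(
                f"ATOM  {serial:5d} {name:<4s} {res3} A{res.index:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {name[0]:>2s}"
            )
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# disorder tracks
# ---------------------------------------------------------------------------

def read_disorder_table(path: str | Path) -> dict[str, DisorderTrack]:
    """Read a disorder-score TSV.

    Columns: ``protein_id``, ``residue_index`` (1-based, contiguous from 1)
    and ``disorder`` in [0, 1].  A two-column file (no ``protein_id``) is
    accepted for a single protein, whose id is taken from the file stem.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if "protein_id" not in df.columns:
        df["protein_id"] = path.stem
    for col in ("residue_index", "disorder"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    tracks: dict[str, DisorderTrack] = {}
    for pid, sub in df.groupby("protein_id", sort=False):
        idx = sub["residue_index"].to_numpy()
        if not np.array_equal(idx, np.arange(1, len(idx) + 1)):
            raise FormatError(f"{path}: {pid}: residue_index not contiguous from 1")
        tracks[str(pid)] = DisorderTrack(str(pid), sub["disorder"].to_numpy(dtype=float))
    return tracks


def write_disorder_table(tracks: Iterable[DisorderTrack], path: str | Path) -> None:
    rows = []
    for t in tracks:
        for i, s in enumerate(t.scores, start=1):
            rows.append((t.protein_id, i, f"{s:.4f}"))
    df = pd.DataFrame(rows, columns=["protein_id", "residue_index", "disorder"])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sequences and annotations
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Minimal FASTA reader: id is the first word of the header."""
    seqs: dict[str, list[str]] = {}
    current: str | None = None
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            current = line[1:].split()[0]
            seqs[current] = []
        else:
            if current is None:
                raise FormatError(f"{path}: sequence data before first header")
            seqs[current].append(line)
    return {k: "".join(v).upper() for k, v in seqs.items()}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for pid, seq in seqs.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


_FEATURE_TYPES = ("TRANSMEM", "DISULFID", "MOD_RES", "CARBOHYD", "LIPID", "LOCALIZATION")
_PTM_BY_FEATURE = {"MOD_RES": "modified_residue", "CARBOHYD": "glycosylation",
                   "LIPID": "lipidation"}


def read_annotation_table(path: str | Path, sequences: dict[str, str]
                          ) -> dict[str, ProteinAnnotations]:
    """Read a UniProt-style flat feature table.

    Columns: ``protein_id``, ``feature_type`` in {TRANSMEM, DISULFID,
    MOD_RES, CARBOHYD, LIPID, LOCALIZATION}, ``start``, ``end`` (1-based
    inclusive; DISULFID rows carry the two bridged cysteines as start/end;
    LOCALIZATION rows carry the label in ``category`` and ignore positions).
    Every protein in `sequences` gets an entry, annotated or not.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    needed = {"protein_id", "feature_type", "start", "end"}
    if not needed.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(needed)}")
    per: dict[str, dict] = {
        pid: {"tm": [], "ss": [], "ptm": {}, "loc": None} for pid in sequences
    }
    for rownum, row in enumerate(df.itertuples(index=False), start=2):
        pid = str(row.protein_id)
        if pid not in per:
            raise FormatError(f"{path}:{rownum}: unknown protein {pid}")
        ftype = row.feature_type
        if ftype not in _FEATURE_TYPES:
            raise FormatError(f"{path}:{rownum}: unknown feature_type {ftype!r}")
        if ftype == "LOCALIZATION":
            per[pid]["loc"] = str(getattr(row, "category", "") or "")
            continue
        start, end = int(row.start), int(row.end)
        if ftype != "DISULFID" and start > end:
            raise FormatError(f"{path}:{rownum}: start {start} > end {end}")
        length = len(sequences[pid])
        if not (1 <= start <= length and 1 <= end <= length):
            raise FormatError(f"{path}:{rownum}: positions outside 1..{length}")
        if ftype == "TRANSMEM":
            per[pid]["tm"].append((start, end))
        elif ftype == "DISULFID":
            per[pid]["ss"].append((start, end))
        else:
            for k in range(start, end + 1):
                per[pid]["ptm"][k] = _PTM_BY_FEATURE[ftype]
    return {
        pid: ProteinAnnotations(
            protein_id=pid, sequence=sequences[pid], tm_ranges=d["tm"],
            disulfide_pairs=d["ss"], ptm_sites=d["ptm"], localization_label=d["loc"],
        )
        for pid, d in per.items()
    }


def write_annotation_table(annotations: Iterable[ProteinAnnotations],
                           path: str | Path) -> None:
    rows = []
    rev_ptm = {v: k for k, v in _PTM_BY_FEATURE.items()}
    for ann in annotations:
        for s, e in ann.tm_ranges:
            rows.append((ann.protein_id, "TRANSMEM", s, e, ""))
        for i, j in ann.disulfide_pairs:
            rows.append((ann.protein_id, "DISULFID", i, j, ""))
        for k in sorted(ann.ptm_sites):
            rows.append((ann.protein_id, rev_ptm[ann.ptm_sites[k]], k, k, ""))
        if ann.localization_label:
            rows.append((ann.protein_id, "LOCALIZATION", 0, 0, ann.localization_label))
    df = pd.DataFrame(rows, columns=["protein_id", "feature_type", "start", "end",
                                     "category"])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# antibody records
# ---------------------------------------------------------------------------

_RECORD_COLUMNS = ["antibody_id", "protein_id", "immunogen_sequence",
                   "outcome_wb", "outcome_ihc", "outcome_icc", "wb_bands"]


def _record_from_mapping(m: dict, where: str) -> AntibodyRecord:
    bands_raw = m.get("wb_bands")
    if bands_raw is None or (isinstance(bands_raw, float) and np.isnan(bands_raw)):
        bands: list[float] | None = None
    elif isinstance(bands_raw, str):
        bands = [float(b) for b in bands_raw.split(";") if b.strip()] if bands_raw.strip() else None
    else:
        bands = [float(b) for b in bands_raw]
    if bands == []:
        bands = None
    if str(m.get("outcome_wb")) != "untested" and bands is None:
        bands = []
    try:
        return AntibodyRecord(
            antibody_id=str(m["antibody_id"]), protein_id=str(m["protein_id"]),
            immunogen_sequence=str(m["immunogen_sequence"]),
            outcome_wb=str(m["outcome_wb"]), outcome_ihc=str(m["outcome_ihc"]),
            outcome_icc=str(m["outcome_icc"]), wb_bands=bands,
        )
    except KeyError as exc:
        raise FormatError(f"{where}: missing field {exc}") from exc
    except FormatError as exc:
        raise FormatError(f"{where}: {exc}") from exc


def read_antibody_table(path: str | Path) -> list[AntibodyRecord]:
    """Read antibody validation records from TSV or JSON.

    TSV columns: antibody_id, protein_id, immunogen_sequence, outcome_wb,
    outcome_ihc, outcome_icc, wb_bands (semicolon-separated kDa values,
    empty unless WB was tested).  JSON: a list of objects with the same
    keys, wb_bands as a list of numbers.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        return [_record_from_mapping(m, f"{path}[{i}]") for i, m in enumerate(data)]
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_RECORD_COLUMNS[:-1]) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for i, row in enumerate(df.to_dict("records"), start=2):
        if row.get("wb_bands", "") == "":
            row["wb_bands"] = None
        records.append(_record_from_mapping(row, f"{path}:{i}"))
    return records


def write_antibody_table(records: Iterable[AntibodyRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        bands = "" if r.wb_bands is None else ";".join(f"{b:.1f}" for b in r.wb_bands)
        rows.append((r.antibody_id, r.protein_id, r.immunogen_sequence,
                     r.outcome_wb, r.outcome_ihc, r.outcome_icc, bands))
    pd.DataFrame(rows, columns=_RECORD_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# profile table and cohort reports
# ---------------------------------------------------------------------------

PROFILE_COLUMNS = ["protein_id", "residue_index", "aa", "ss3", "rsa", "buried",
                   "contacts", "disorder", "is_tm", "in_disulfide", "is_ptm"]
_PROFILE_FLOATS = {"rsa": 4, "disorder": 4}


def write_profile_table(profiles: pd.DataFrame, path: str | Path) -> None:
    """Write a per-residue feature table (deterministic columns, fixed precision)."""
    if profiles.empty:
        warnings.warn(f"{path}: writing header-only profile table", stacklevel=2)
        pd.DataFrame(columns=PROFILE_COLUMNS).to_csv(path, sep="\t", index=False)
        return
    df = profiles.loc[:, PROFILE_COLUMNS].copy()
    for col, prec in _PROFILE_FLOATS.items():
        df[col] = df[col].map(lambda v: "" if pd.isna(v) else f"{v:.{prec}f}")
    df.to_csv(path, sep="\t", index=False)


def read_profile_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != PROFILE_COLUMNS:
        raise FormatError(f"{path}: unexpected profile columns {list(df.columns)}")
    return df


def write_cohort_report(tables, out_prefix: str | Path) -> None:
    """Write cohort tables as one TSV plus one JSON next to each other.

    `tables` is an iterable of cohort_stats.CohortTable.
    """
    tables = list(tables)
    out_prefix = Path(out_prefix)
    rows = []
    blob = []
    for t in tables:
        for r in t.rows:
            rows.append((t.grouping_variable, r.group_label, r.n_total, r.n_success,
                         f"{r.success_rate:.4f}"))
        blob.append(t.to_dict())
    if not rows:
        warnings.warn(f"{out_prefix}: empty cohort report", stacklevel=2)
    pd.DataFrame(rows, columns=["grouping", "group", "n_total", "n_success",
                                "success_rate"]).to_csv(
        out_prefix.with_suffix(".tsv"), sep="\t", index=False)
    out_prefix.with_suffix(".json").write_text(json.dumps(blob, indent=2) + "\n")
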