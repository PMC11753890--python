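"""Readers and writers for every on-disk artifact the pipeline touches.

All profile-shaped data (PSSM, energy-contact matrices) is reordered on load
to a single canonical amino-acid column order — the PSI-BLAST header order
``A R N D C Q E G H I L K M F P S T W Y V`` — so that downstream transforms
can never silently misalign columns between views.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

#: Canonical amino-acid order (PSI-BLAST ASCII PSSM header order).
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

#: Nonstandard residue letters accepted under the mapping policy.
NONSTANDARD = set("BZXUOJ")

SCHEMA_VERSION = 1


class FormatError(ValueError):
    """Raised when an input file violates its expected layout."""


def normalize_sequence(seq: str, rec_id: str = "?", policy: str = "map_to_x") -> str:
    """Upper-case a sequence and resolve nonstandard residues.

    policy="map_to_x" maps B/Z/X/U/O/J to "X"; policy="strict" rejects any
    letter outside the 20 standard amino acids, naming the record and the
    offending character.
    """
    seq = seq.upper().replace("*", "").replace("-", "")
    out = []
    for ch in seq:
        if ch in AA_INDEX:
            out.append(ch)
        elif policy == "map_to_x" and ch in NONSTANDARD:
            out.append("X")
        else:
            raise FormatError(
                f"record {rec_id!r}: illegal residue {ch!r} "
                f"(policy={policy!r})"
            )
    if not out:
        raise FormatError(f"record {rec_id!r}: empty sequence")
    return "".join(out)


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with identifier; houses the length L."""

    id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ProfileMatrix:
    """L x 20 real matrix over the canonical amino-acid columns.

    Holds either a PSSM (one log-odds row per residue) or an RECM-T (one
    energy-contact row per residue).  ``residues`` retains the per-row
    residue letters when the source file provides them, enabling
    cross-validation against the paired sequence.
    """

    values: np.ndarray
    residues: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 20:
            raise FormatError(
                f"profile matrix must be L x 20, got {self.values.shape}"
            )
        if not np.isfinite(self.values).all():
            raise FormatError("profile matrix contains non-finite entries")
        if self.residues is not None and len(self.residues) != len(self.values):
            raise FormatError("residue column length does not match matrix rows")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class EnergyContactMatrix:
    """Symmetric 20 x 20 residue-wise contact-energy table.

    Diagonal entries are self-contact energies; off-diagonal entries are
    pairwise contact energies between two different standard amino acids.
    """

    values: np.ndarray
    labels: str = AA_ORDER

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (20, 20):
            raise FormatError(
                f"energy matrix must be 20 x 20, got {self.values.shape}"
            )

    def row(self, residue: str) -> np.ndarray:
        """Energy row for one residue; "X" maps to the column-wise mean row."""
        if residue == "X":
            return self.values.mean(axis=0)
        try:
            return self.values[AA_INDEX[residue]]
        except KeyError:
            raise FormatError(f"unresolvable residue {residue!r}") from None


@dataclass
class FeatureTable:
    """n x D feature matrix partitioned into named blocks (views).

    D equals the sum of ``block_dims``; ``labels`` (0/1), when present, align
    with ``ids`` row-wise.
    """

    ids: list[str]
    block_names: list[str]
    block_dims: list[int]
    matrix: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if len(set(self.ids)) != len(self.ids):
            raise FormatError("duplicate ids in feature table")
        if self.matrix.shape != (len(self.ids), sum(self.block_dims)):
            raise FormatError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.ids)} ids x {sum(self.block_dims)} features"
            )
        if len(self.block_names) != len(self.block_dims):
            raise FormatError("block_names and block_dims length mismatch")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (len(self.ids),):
                raise FormatError("labels length mismatch")
            if not np.isin(self.labels, (0, 1)).all():
                raise FormatError("labels must be 0/1")

    @property
    def n_features(self) -> int:
        return int(sum(self.block_dims))

    def block_slices(self) -> dict[str, slice]:
        out, start = {}, 0
        for name, dim in zip(self.block_names, self.block_dims):
            out[name] = slice(start, start + dim)
            start += dim
        return out

    def block(self, name: str) -> np.ndarray:
        return self.matrix[:, self.block_slices()[name]]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path, policy: str = "map_to_x") -> list[ProteinRecord]:
    """Read a FASTA file into validated :class:`ProteinRecord` objects."""
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            ProteinRecord(rec.id, normalize_sequence(str(rec.seq), rec.id, policy))
        )
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(path, records: list[ProteinRecord], width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM
# ---------------------------------------------------------------------------

def read_pssm_ascii(
    path,
    sequence: str | None = None,
    columns: str = "log_odds",
) -> ProfileMatrix:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file into an L x 20 profile.

    ``columns`` selects the log-odds block (default, standard practice) or
    the ``"percentages"`` block.  When ``sequence`` is given, the file's
    residue column must spell it (after nonstandard-residue mapping on both
    sides), otherwise a mismatch error is raised.
    """
    if columns not in ("log_odds", "percentages"):
        raise ValueError(f"unknown column block {columns!r}")
    rows, residues = [], []
    with open(path) as fh:
        lines = fh.readlines()
    header_order = None
    for lineno, line in enumerate(lines, start=1):
        parts = line.split()
        if not parts:
            continue
        # The column-label header: 40 single-letter residue names.
        if header_order is None:
            if len(parts) >= 40 and all(p in AA_INDEX for p in parts[:40]):
                header_order = parts[:20]
            continue
        if not parts[0].isdigit():
            continue  # trailing statistics (lambda/K) or footer
        if len(parts) < 22:
            raise FormatError(
                f"{path}:{lineno}: expected >= 22 fields in PSSM row, "
                f"got {len(parts)}"
            )
        residues.append(parts[1])
        block = parts[2:22] if columns == "log_odds" else parts[22:42]
        try:
            rows.append([float(v) for v in block])
        except ValueError:
            raise FormatError(
                f"{path}:{lineno}: non-numeric value in PSSM row"
            ) from None
        if len(block) != 20:
            raise FormatError(
                f"{path}:{lineno}: expected 20 values, got {len(block)}"
            )
    if header_order is None or not rows:
        raise FormatError(f"{path}: no PSSM data rows found")
    values = np.array(rows, dtype=float)
    # Reorder columns to canonical order if the header deviates.
    if "".join(header_order) != AA_ORDER:
        perm = [header_order.index(a) for a in AA_ORDER]
        values = values[:, perm]
    res_str = "".join(residues)
    if sequence is not None:
        mapped = normalize_sequence(res_str, policy="map_to_x")
        expect = normalize_sequence(sequence, policy="map_to_x")
        if mapped != expect:
            raise FormatError(
                f"{path}: PSSM residue column {res_str!r} does not match "
                f"paired sequence"
            )
    return ProfileMatrix(values, residues=res_str)


_PSSM_HEADER = (
    "\n"
    "Last position-specific scoring matrix computed, weighted observed "
    "percentages rounded down, information per position, and relative "
    "weight of gapless real matches to pseudocounts\n"
)


def write_pssm_ascii(path, profile: ProfileMatrix, sequence: str) -> None:
    """Write a profile in the PSI-BLAST ``-out_ascii_pssm`` dialect.

    Emits the two header lines, one row per residue with position, residue
    letter, 20 integer log-odds, 20 percentages (zeros), and the two
    trailing per-row statistics, so that the file round-trips through
    :func:`read_pssm_ascii`.
    """
    vals = np.rint(profile.values).astype(int)
    with open(path, "w") as fh:
        fh.write(_PSSM_HEADER)
        labels = "  ".join(AA_ORDER)
        fh.write("            " + labels + "   " + labels + "\n")
        for i, (res, row) in enumerate(zip(sequence, vals), start=1):
            lo = " ".join(f"{v:3d}" for v in row)
            pc = " ".join(f"{0:3d}" for _ in row)
            fh.write(f"{i:5d} {res} {lo}  {pc}  0.00 0.00\n")
        fh.write("\n                      K         Lambda\n")


# ---------------------------------------------------------------------------
# Energy-contact matrix (labelled TSV)
# ---------------------------------------------------------------------------

def read_energy_matrix(path, on_asymmetry: str = "warn", tol: float = 1e-9) -> EnergyContactMatrix:
    """Load a labelled 20 x 20 TSV of residue contact energies.

    Rows and columns are reordered to the canonical amino-acid order by
    label, so shuffled input orders are handled.  Asymmetric tables beyond
    ``tol`` warn by default (``on_asymmetry="error"`` to reject).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip().str.upper()
    df.columns = df.columns.astype(str).str.strip().str.upper()
    if df.shape != (20, 20):
        raise FormatError(f"{path}: energy matrix must be 20 x 20, got {df.shape}")
    missing = [a for a in AA_ORDER if a not in df.index or a not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing amino-acid labels {missing}")
    df = df.loc[list(AA_ORDER), list(AA_ORDER)]
    values = df.to_numpy(dtype=float)
    asym = np.abs(values - values.T).max()
    if asym > tol:
        msg = f"{path}: energy matrix asymmetric (max |e_ij - e_ji| = {asym:g})"
        if on_asymmetry == "error":
            raise FormatError(msg)
        warnings.warn(msg)
    return EnergyContactMatrix(values)


def write_energy_matrix(path, ecm: EnergyContactMatrix) -> None:
    df = pd.DataFrame(ecm.values, index=list(AA_ORDER), columns=list(AA_ORDER))
    df.to_csv(path, sep="\t", float_format="%.6g")


# ---------------------------------------------------------------------------
# FeatureTable TSV (two-row header: block name, within-block column index)
# ---------------------------------------------------------------------------

def write_feature_table(path, table: FeatureTable) -> None:
    with open(path, "w") as fh:
        names, idxs = ["id"], [""]
        for name, dim in zip(table.block_names, table.block_dims):
            names.extend([name] * dim)
            idxs.extend(str(i) for i in range(dim))
        if table.labels is not None:
            names.append("label")
            idxs.append("")
        fh.write("\t".join(names) + "\n")
        fh.write("\t".join(idxs) + "\n")
        for i, rid in enumerate(table.ids):
            row = [rid] + [repr(float(v)) for v in table.matrix[i]]
            if table.labels is not None:
                row.append(str(int(table.labels[i])))
            fh.write("\t".join(row) + "\n")


def read_feature_table(path) -> FeatureTable:
    with open(path) as fh:
        names = fh.readline().rstrip("\n").split("\t")
        fh.readline()  # within-block indices; implied by block order
        ids, rows, labels = [], [], []
    has_labels = names and names[-1] == "label"
    feat_names = names[1 : -1 if has_labels else None]
    block_names, block_dims = [], []
    for name in feat_names:
        if block_names and block_names[-1] == name:
            block_dims[-1] += 1
        else:
            block_names.append(name)
            block_dims.append(1)
    with open(path) as fh:
        fh.readline()
        fh.readline()
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                continue
            ids.append(parts[0])
            if has_labels:
                rows.append([float(v) for v in parts[1:-1]])
                labels.append(int(parts[-1]))
            else:
                rows.append([float(v) for v in parts[1:]])
    return FeatureTable(
        ids,
        block_names,
        block_dims,
        np.array(rows, dtype=float),
        np.array(labels, dtype=int) if has_labels else None,
    )


# ---------------------------------------------------------------------------
# ModelBundle
# ---------------------------------------------------------------------------

@dataclass
class ModelBundle:
    """Everything needed to reproduce prediction: a directory with a JSON
    manifest plus binary parameter files (``.npz``).

    Fields mirror the fitted pipeline stages: QLC normalization statistics,
    the learned view-weight vector, the selected-feature mask, the
    classifier's parameter arrays, and a snapshot of the resolved config.
    """

    qlc_mean: np.ndarray | None = None
    qlc_std: np.ndarray | None = None
    weights: np.ndarray | None = None
    mask: np.ndarray | None = None
    classifier_params: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    schema_version: int = SCHEMA_VERSION

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for key in ("qlc_mean", "qlc_std", "weights"):
            val = getattr(self, key)
            if val is not None:
                arrays[key] = np.asarray(val)
        for key, val in self.classifier_params.items():
            arrays[f"clf__{key}"] = np.asarray(val)
        np.savez(directory / "params.npz", **arrays)
        if self.mask is not None:
            # 0-based selected indices, newline-delimited
            idx = np.flatnonzero(np.asarray(self.mask))
            (directory / "mask.txt").write_text(
                "\n".join(str(i) for i in idx) + "\n"
            )
            mask_len = int(len(np.asarray(self.mask)))
        else:
            mask_len = None
        manifest = {
            "schema_version": self.schema_version,
            "config": self.config,
            "mask_length": mask_len,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory) -> "ModelBundle":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        if manifest["schema_version"] != SCHEMA_VERSION:
            raise FormatError(
                f"bundle schema {manifest['schema_version']} != {SCHEMA_VERSION}"
            )
        data = np.load(directory / "params.npz")
        clf = {
            k[len("clf__"):]: data[k] for k in data.files if k.startswith("clf__")
        }
        mask = None
        if manifest["mask_length"] is not None:
            mask = np.zeros(manifest["mask_length"], dtype=bool)
            txt = (directory / "mask.txt").read_text().split()
            mask[[int(i) for i in txt]] = True
        return cls(
            qlc_mean=data["qlc_mean"] if "qlc_mean" in data.files else None,
            qlc_std=data["qlc_std"] if "qlc_std" in data.files else None,
            weights=data["weights"] if "weights" in data.files else None,
            mask=mask,
            classifier_params=clf,
            config=manifest["config"],
            schema_version=manifest["schema_version"],
        )
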