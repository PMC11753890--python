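"""Qualitative-characteristics (QLC) descriptor: CTD physicochemical features.

Each of seven physicochemical attributes (hydrophobicity, normalized van der
Waals volume, polarity, polarizability, charge, secondary structure, solvent
accessibility) partitions the 20 standard amino acids into three groups.  A
sequence is re-encoded as a string over {1,2,3} per attribute, from which
three index families are computed:

* Composition (C, 3 values): percentage of residues in each group.
* Transition (T, 3 values): percentage of adjacent residue pairs whose two
  members fall in two different groups, for each unordered group pair.
* Distribution (D, 15 values): for each group, the sequence positions (as a
  percentage of length) at which the first, 25%, 50%, 75% and last
  occurrences of that group are found.

Per attribute this yields 3 + 3 + 15 = 21 features; over seven attributes the
QLC descriptor has dimension 147.  Residues mapped to "X" by the
nonstandard-residue policy are excluded, with the effective length adjusted.

The descriptor is z-score normalized per feature across the training set
(statistics persisted for prediction time); a min-max variant is available.
"""

from __future__ import annotations

import math
from importlib import resources

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from targetclp.io_formats import FeatureTable, ProteinRecord

#: Attribute order fixing the layout of the 147-vector.
PROPERTY_ORDER = (
    "hydrophobicity",
    "normalized_vdw_volume",
    "polarity",
    "polarizability",
    "charge",
    "secondary_structure",
    "solvent_accessibility",
)

QLC_DIM = 147  # 7 properties x (3 C + 3 T + 15 D)


def load_groupings(path=None) -> dict[str, dict[str, str]]:
    """Load the three-group partition tables (overridable by a TSV path)."""
    if path is None:
        source = resources.files("targetclp.data").joinpath("ctd_groups.tsv")
        text = source.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    lines = [ln.split("\t") for ln in text.strip().splitlines()]
    header, rows = lines[0], lines[1:]
    assert header[:4] == ["property", "group1", "group2", "group3"]
    tables = {}
    for prop, g1, g2, g3 in rows:
        groups = {"1": g1.strip(), "2": g2.strip(), "3": g3.strip()}
        members = "".join(groups.values())
        if len(set(members)) != 20 or len(members) != 20:
            raise ValueError(f"grouping for {prop!r} is not a partition of the 20 amino acids")
        tables[prop] = groups
    return tables


_DEFAULT_GROUPS = load_groupings()


def encode_groups(record: ProteinRecord, grouping: dict[str, str]) -> str:
    """Re-encode a sequence as its group labels over {1,2,3}; "X" dropped."""
    lookup = {aa: label for label, members in grouping.items() for aa in members}
    encoded = "".join(lookup[res] for res in record.sequence if res != "X")
    if not encoded:
        raise ValueError(f"record {record.id!r}: no resolvable residues")
    return encoded


def ctd_composition(groups: str) -> np.ndarray:
    """Percentage composition of each of the three groups (sums to 100)."""
    n = len(groups)
    return np.array([groups.count(g) / n * 100.0 for g in "123"])


def ctd_transition(groups: str) -> np.ndarray:
    """Percentage of adjacent pairs transitioning between two distinct groups,
    for unordered pairs (1,2), (1,3), (2,3)."""
    if len(groups) < 2:
        return np.zeros(3)
    pairs = list(zip(groups, groups[1:]))
    n_adj = len(pairs)
    out = []
    for a, b in (("1", "2"), ("1", "3"), ("2", "3")):
        count = sum(1 for x, y in pairs if (x, y) in ((a, b), (b, a)))
        out.append(count / n_adj * 100.0)
    return np.array(out)


def ctd_distribution(groups: str) -> np.ndarray:
    """First/25%/50%/75%/last occurrence positions of each group, as
    percentages of the sequence length (15 values; absent group -> zeros).

    The q-percentile occurrence of a group with n_g members is its
    ceil(q * n_g)-th occurrence (1-based positions); the "first" slot is the
    first occurrence.
    """
    n = len(groups)
    out = []
    for g in "123":
        positions = [i + 1 for i, ch in enumerate(groups) if ch == g]
        n_g = len(positions)
        if n_g == 0:
            out.extend([0.0] * 5)
            continue
        for q in (0.0, 0.25, 0.50, 0.75, 1.0):
            k = max(1, math.ceil(q * n_g))
            out.append(positions[k - 1] / n * 100.0)
    return np.array(out)


def qlc_vector(record: ProteinRecord, groupings=None) -> np.ndarray:
    """The raw (unnormalized) 147-dimensional QLC descriptor."""
    tables = _DEFAULT_GROUPS if groupings is None else groupings
    parts = []
    for prop in PROPERTY_ORDER:
        groups = encode_groups(record, tables[prop])
        parts.extend([ctd_composition(groups), ctd_transition(groups), ctd_distribution(groups)])
    vec = np.concatenate(parts)
    assert vec.shape == (QLC_DIM,)
    return vec


class QLCNormalizer(TransformerMixin, BaseEstimator):
    """Per-feature normalization with statistics learned on training data.

    mode="zscore" (default) applies z = (x - mean) / std with the sample
    (ddof=1) standard deviation; constant features get std set to 1 (flagged
    in ``constant_mask_``) so they map to zero.  mode="minmax" rescales each
    feature to [0, 1] over the training range.
    """

    def __init__(self, mode: str = "zscore"):
        self.mode = mode

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if self.mode == "zscore":
            self.mean_ = X.mean(axis=0)
            std = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
            self.constant_mask_ = std == 0
            self.scale_ = np.where(self.constant_mask_, 1.0, std)
        elif self.mode == "minmax":
            self.mean_ = X.min(axis=0)
            rng = X.max(axis=0) - X.min(axis=0)
            self.constant_mask_ = rng == 0
            self.scale_ = np.where(self.constant_mask_, 1.0, rng)
        else:
            raise ValueError(f"unknown normalization mode {self.mode!r}")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) / self.scale_


def fit_apply_normalization(table: FeatureTable, stats: QLCNormalizer | None = None):
    """Normalize a feature table; fit stats when none are given.

    Returns ``(normalized_table, stats)``.  Call with fitted ``stats`` at
    prediction time so no test-set information leaks into the statistics.
    """
    if stats is None:
        stats = QLCNormalizer().fit(table.matrix)
    matrix = stats.transform(table.matrix)
    out = FeatureTable(table.ids, table.block_names, list(table.block_dims), matrix, table.labels)
    return out, stats
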