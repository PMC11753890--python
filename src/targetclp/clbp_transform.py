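"""Completed local binary pattern (CLBP) texture descriptors of profile matrices.

A profile matrix (PSSM or RECM-T, both L x 20) is min-max scaled to an 8-bit
"image", then each interior pixel is described by three local operators over
its 3 x 3 neighborhood (radius R=1, N=8 neighbors):

* C — a single bit comparing the center intensity against the global image
  mean T;
* S — an 8-bit code of the signs of (neighbor - center) differences;
* M — an 8-bit code thresholding |neighbor - center| magnitudes against the
  image-wide mean magnitude T_m.

The three code maps are reduced to a 236-dimensional descriptor by
uniform-pattern (u2) histogramming: 59 bins for S, 59 for M, and a joint
118-bin M-by-C histogram.  For N=8 there are 58 uniform circular codes (at
most two 0/1 transitions); all non-uniform codes share one catch-all bin.

The descriptor is invariant to positive affine rescaling of the input matrix
(min-max scaling removes gain and offset), and each histogram part sums to
the number of interior centers, (L-2) * 18.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from targetclp.io_formats import (
    EnergyContactMatrix,
    ProfileMatrix,
    ProteinRecord,
)

#: Fixed neighbor order: n=0 at the east neighbor, proceeding counter-clockwise.
#: Offsets are (row, col) with rows increasing downward.
NEIGHBOR_OFFSETS = (
    (0, 1),    # E
    (-1, 1),   # NE
    (-1, 0),   # N
    (-1, -1),  # NW
    (0, -1),   # W
    (1, -1),   # SW
    (1, 0),    # S
    (1, 1),    # SE
)

#: Histogram decomposition identifier recorded on every descriptor.
SCHEME = "S_u2(59)+M_u2(59)+M_u2xC(118)"


def _u2_bin_table(n_bits: int = 8) -> np.ndarray:
    """Map each code 0..2^N-1 to its u2 histogram bin.

    Uniform codes (<= 2 circular 0/1 transitions) get bins 0..57 in ascending
    code order; every non-uniform code maps to the catch-all bin 58.
    """
    size = 1 << n_bits
    bins = np.empty(size, dtype=np.int64)
    uniform = []
    for code in range(size):
        transitions = bin(code ^ ((code >> 1) | ((code & 1) << (n_bits - 1)))).count("1")
        if transitions <= 2:
            uniform.append(code)
    lookup = {code: i for i, code in enumerate(uniform)}
    catch_all = len(uniform)
    for code in range(size):
        bins[code] = lookup.get(code, catch_all)
    return bins


_U2_BINS = _u2_bin_table(8)
N_U2_BINS = int(_U2_BINS.max()) + 1  # 59 for N=8


@dataclass
class CLBPCodeMaps:
    """Per-center C/S/M codes on the (L-2) x 18 interior grid."""

    c_map: np.ndarray
    s_map: np.ndarray
    m_map: np.ndarray

    @property
    def n_centers(self) -> int:
        return int(self.c_map.size)


@dataclass
class CLBPDescriptor:
    """236-dimensional CLBP histogram descriptor."""

    vector: np.ndarray
    scheme: str = SCHEME

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)
        if self.vector.shape != (236,):
            raise ValueError(f"CLBP descriptor must have 236 entries, got {self.vector.shape}")


def scale_to_image(matrix: ProfileMatrix | np.ndarray) -> np.ndarray:
    """Min-max scale a profile matrix to integer intensities in [0, 255].

    x' = round(255 * (x - min) / (max - min)), rounding half to even; a
    constant matrix maps to the all-zero image.
    """
    values = matrix.values if isinstance(matrix, ProfileMatrix) else np.asarray(matrix, dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros(values.shape, dtype=np.int64)
    scaled = 255.0 * (values - lo) / (hi - lo)
    return np.rint(scaled).astype(np.int64)


def clbp_code_maps(image: np.ndarray, radius: int = 1, neighbors: int = 8) -> CLBPCodeMaps:
    """Compute C, S and M code maps over all interior centers of an image.

    The center bit is 1 iff the center intensity is >= the global image mean
    T.  The S code sets bit n iff neighbor_n - center >= 0.  The M code sets
    bit n iff |neighbor_n - center| >= T_m, where T_m is the mean absolute
    difference over every (center, neighbor) pair of the image.
    """
    if radius != 1 or neighbors != 8:
        raise ValueError("only radius=1 with 8 neighbors is supported")
    img = np.asarray(image, dtype=np.int64)
    rows, cols = img.shape
    if rows < 3 or cols < 3:
        raise ValueError("sequence too short for CLBP window (need L >= 3)")
    center = img[1:-1, 1:-1]
    diffs = np.stack(
        [img[1 + dr : rows - 1 + dr, 1 + dc : cols - 1 + dc] - center
         for dr, dc in NEIGHBOR_OFFSETS]
    )  # (8, rows-2, cols-2)
    t_global = img.mean()
    t_mag = np.abs(diffs).mean()
    c_map = (center >= t_global).astype(np.int64)
    weights = (1 << np.arange(8, dtype=np.int64))[:, None, None]
    s_map = ((diffs >= 0) * weights).sum(axis=0)
    m_map = ((np.abs(diffs) >= t_mag) * weights).sum(axis=0)
    return CLBPCodeMaps(c_map=c_map, s_map=s_map, m_map=m_map)


def clbp_histogram(maps: CLBPCodeMaps, normalize: bool = False) -> CLBPDescriptor:
    """Bin the code maps into the 236-dimensional u2 histogram descriptor.

    Layout: 59 u2 bins of the S map, 59 u2 bins of the M map, then the joint
    M-by-C histogram (59 M bins for centers with C=0 followed by 59 for C=1).
    Counts by default; ``normalize=True`` divides each 59/59/118 part by the
    number of centers.
    """
    s_bins = _U2_BINS[maps.s_map.ravel()]
    m_bins = _U2_BINS[maps.m_map.ravel()]
    c_bits = maps.c_map.ravel()
    hist_s = np.bincount(s_bins, minlength=N_U2_BINS).astype(float)
    hist_m = np.bincount(m_bins, minlength=N_U2_BINS).astype(float)
    joint = np.bincount(c_bits * N_U2_BINS + m_bins, minlength=2 * N_U2_BINS).astype(float)
    vec = np.concatenate([hist_s, hist_m, joint])
    if normalize and maps.n_centers:
        vec = vec / maps.n_centers
    return CLBPDescriptor(vec)


def pssm_clbp(matrix: ProfileMatrix, normalize: bool = False) -> CLBPDescriptor:
    """Full PSSM-CLBP transform: scale to image, code maps, histogram."""
    return clbp_histogram(clbp_code_maps(scale_to_image(matrix)), normalize=normalize)


def build_recm_t(record: ProteinRecord, ecm: EnergyContactMatrix) -> ProfileMatrix:
    """Build the L x 20 RECM-T profile: row j is the energy-contact vector of
    residue j against all 20 amino acids (canonical column order)."""
    if not record.sequence:
        raise ValueError(f"record {record.id!r}: empty sequence")
    rows = np.stack([ecm.row(res) for res in record.sequence])
    return ProfileMatrix(rows, residues=record.sequence)


def recm_clbp(record: ProteinRecord, ecm: EnergyContactMatrix, normalize: bool = False) -> CLBPDescriptor:
    """RECM-CLBP transform: build RECM-T, then apply the CLBP pipeline."""
    return pssm_clbp(build_recm_t(record, ecm), normalize=normalize)
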