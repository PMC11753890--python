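"""Seeded generators for every input the pipeline consumes.

These emulate the pipeline's external inputs — protein sequences, PSI-BLAST
style profile matrices, a symmetric residue contact-energy table, and
two-class multi-view feature sets with planted informative dimensions — so
that every stage is testable without databases, search tools or pretrained
weights.  The profile noise model is intentionally simple: the texture
transform only needs a realistic value range and per-row structure, not
evolutionary fidelity.  All generators are pure functions of their
parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from targetclp.io_formats import (
    AA_INDEX,
    AA_ORDER,
    EnergyContactMatrix,
    FeatureTable,
    ProfileMatrix,
    ProteinRecord,
)


@dataclass
class SynthSpec:
    """Study-condition parameters for the synthetic generators."""

    n_sequences: int = 60
    length_range: tuple[int, int] = (50, 200)
    block_names: tuple = ("ESM", "PSSM-CLBP", "QLC", "RECM-CLBP")
    block_dims: tuple = (1280, 236, 147, 236)
    informative: dict = field(default_factory=dict)  # block name -> index list
    shift: float = 2.0
    noise_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_range[0] < 3:
            raise ValueError("sequences must have length >= 3 (CLBP window)")
        if self.shift < 0:
            raise ValueError("class-mean shift must be >= 0")


def gen_sequences(spec: SynthSpec) -> list[ProteinRecord]:
    """i.i.d. uniform-composition random sequences; ids seq0001, ..."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    records = []
    for i in range(spec.n_sequences):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(AA_ORDER[j] for j in rng.integers(0, 20, size=length))
        records.append(ProteinRecord(f"seq{i + 1:04d}", seq))
    return records


def gen_profile(record: ProteinRecord, seed: int = 0) -> ProfileMatrix:
    """Synthetic stand-in for a PSI-BLAST log-odds profile.

    Row j favors the observed residue: +4 on its own column, -1 elsewhere,
    plus integer-rounded Gaussian noise (sigma = 2), clamped to [-15, 15]
    (the value range of real ASCII PSSM files).
    """
    rng = np.random.default_rng(seed)
    L = len(record.sequence)
    base = np.full((L, 20), -1.0)
    for j, res in enumerate(record.sequence):
        col = AA_INDEX.get(res)
        if col is not None:
            base[j, col] = 4.0
    noisy = base + np.rint(rng.normal(0.0, 2.0, size=(L, 20)))
    values = np.clip(noisy, -15, 15)
    return ProfileMatrix(values, residues=record.sequence)


def gen_energy_matrix(seed: int = 0) -> EnergyContactMatrix:
    """Synthetic symmetric 20 x 20 contact-energy table.

    Entries are negative-dominated and lie in a plausible contact-energy
    range [-8, 2] (real statistical contact potentials are mostly negative,
    favourable, with a few repulsive pairs).  Placeholder for a published
    energy table, which is a runtime input of the real pipeline.
    """
    rng = np.random.default_rng(seed)
    raw = rng.uniform(-7.5, 1.5, size=(20, 20))
    values = (raw + raw.T) / 2.0
    return EnergyContactMatrix(values)


def gen_multiview_dataset(spec: SynthSpec) -> FeatureTable:
    """Two-class multi-view Gaussian feature set with planted signal.

    Each view is an isotropic Gaussian block (scale ``noise_scale``); the
    dimensions listed in ``spec.informative`` (per view) have their class-1
    mean shifted by ``spec.shift``, so view-level signal-to-noise is
    controlled per view and weighting the views demonstrably matters.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_sequences
    labels = np.array([0, 1] * (n // 2) + [0] * (n % 2))
    rng.shuffle(labels)
    blocks = []
    for name, dim in zip(spec.block_names, spec.block_dims):
        block = rng.normal(0.0, spec.noise_scale, size=(n, dim))
        for idx in spec.informative.get(name, ()):
            block[labels == 1, idx] += spec.shift
        blocks.append(block)
    return FeatureTable(
        ids=[f"s{i + 1:04d}" for i in range(n)],
        block_names=list(spec.block_names),
        block_dims=[int(d) for d in spec.block_dims],
        matrix=np.concatenate(blocks, axis=1),
        labels=labels,
    )
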