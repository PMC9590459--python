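"""Seeded synthetic inputs for every pipeline stage.

Everything the pipeline consumes can be generated here without downloads:
MSAs Gibbs-sampled from a known sparse Potts model (with planted couplings
and conserved columns), toy helical structures with a placed ligand atom,
and chromatogram series of Gaussian peaks with optional noise.  All
generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from enzdesign.conservation import Alignment
from enzdesign.errors import ParameterError
from enzdesign.msquant import SpectraSeries
from enzdesign.structure import Atom, Structure


# ---------------------------------------------------------------------------
# Potts-sampled MSAs


@dataclass
class MsaSpec:
    """Ground-truth model for a sampled alignment.

    ``alphabet`` defaults to an 8-letter projection for fast recovery tests;
    ``conserved`` maps 1-based columns to their favored residue, and
    ``planted_pairs`` lists 1-based column pairs given a diagonal coupling of
    strength ``beta``.
    """

    L: int = 30
    N: int = 2000
    alphabet: str = "ACDEFGHI"
    conserved: dict[int, str] = field(default_factory=dict)
    field_strength: float = 2.0
    planted_pairs: list[tuple[int, int]] = field(default_factory=list)
    beta: float = 1.0
    burn_in: int = 1000
    thin: int = 10
    n_chains: int | None = None  # defaults to N (independent chains)


def _gibbs_sample(
    h: np.ndarray,
    neighbors: list[list[tuple[int, np.ndarray]]],
    n_chains: int,
    n_sweeps_burn: int,
    samples_needed: int,
    thin: int,
    rng: np.random.Generator,
) -> np.ndarray:
    L, q = h.shape
    x = rng.integers(0, q, size=(n_chains, L))

    def sweep() -> None:
        for i in range(L):
            logits = np.broadcast_to(h[i], (n_chains, q)).copy()
            for j, Jij in neighbors[i]:
                logits += Jij[:, x[:, j]].T
            logits -= logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=1, keepdims=True)
            u = rng.random(n_chains)
            x[:, i] = (u[:, None] > np.cumsum(p, axis=1)).sum(axis=1)

    for _ in range(n_sweeps_burn):
        sweep()
    if n_chains >= samples_needed:
        return x[:samples_needed].copy()
    samples = [x.copy()]
    have = n_chains
    while have < samples_needed:
        for _ in range(thin):
            sweep()
        samples.append(x.copy())
        have += n_chains
    return np.concatenate(samples, axis=0)[:samples_needed]


def sample_potts_msa(spec: MsaSpec, seed: int) -> tuple[Alignment, dict]:
    """Gibbs-sample an alignment from the spec's sparse Potts model.

    Returns the alignment plus a ground-truth record (planted pairs,
    conserved columns, parameters).  With the default one-chain-per-sequence
    setting, samples are independent after burn-in.
    """
    if spec.beta < 0:
        raise ParameterError("beta must be non-negative")
    if spec.L < 2 or spec.N < 1:
        raise ParameterError("need L >= 2 and N >= 1")
    q = len(spec.alphabet)
    planted0 = [(i - 1, j - 1) for i, j in spec.planted_pairs]
    conserved_cols = {c - 1 for c in spec.conserved}
    for i, j in planted0:
        if not (0 <= i < spec.L and 0 <= j < spec.L) or i == j:
            raise ParameterError(f"bad planted pair ({i + 1}, {j + 1})")
        if i in conserved_cols or j in conserved_cols:
            raise ParameterError("planted pairs must be disjoint from conserved columns")

    h = np.zeros((spec.L, q))
    for col, res in spec.conserved.items():
        h[col - 1, spec.alphabet.index(res)] = spec.field_strength
    Jdiag = spec.beta * np.eye(q)
    neighbors: list[list[tuple[int, np.ndarray]]] = [[] for _ in range(spec.L)]
    for i, j in planted0:
        neighbors[i].append((j, Jdiag))
        neighbors[j].append((i, Jdiag.T))

    rng = np.random.default_rng(seed)
    n_chains = spec.n_chains or spec.N
    enc = _gibbs_sample(h, neighbors, n_chains, spec.burn_in, spec.N, spec.thin, rng)
    rows = ["".join(spec.alphabet[a] for a in row) for row in enc]
    aln = Alignment(ids=[f"s{n:05d}" for n in range(spec.N)], rows=rows)
    truth = {
        "seed": seed,
        "alphabet": spec.alphabet,
        "planted_pairs": sorted(tuple(sorted(p)) for p in spec.planted_pairs),
        "conserved": dict(spec.conserved),
        "beta": spec.beta,
        "field_strength": spec.field_strength,
    }
    return aln, truth


# ---------------------------------------------------------------------------
# toy structures


@dataclass
class StructureSpec:
    n_residues: int = 20
    ligand_offset: float = 5.0
    ligand_residue: int | None = None  # 1-based; defaults to the middle residue
    residue_name: str = "ALA"
    ligand_name: str = "LIG"


HELIX_RISE = 1.5  # Å per residue
HELIX_TWIST = 100.0  # degrees per residue
CA_RADIUS = 2.3  # Å
CB_RADIUS = 3.8  # Å


def make_toy_structure(spec: StructureSpec) -> Structure:
    """Ideal α-helix of CA/CB pseudo-atoms plus one HETATM ligand atom.

    The ligand atom sits ``ligand_offset`` Å radially outward from the chosen
    residue's CB.
    """
    n = spec.n_residues
    if n < 4:
        raise ParameterError("need at least 4 residues")
    lig_res = spec.ligand_residue if spec.ligand_residue is not None else (n // 2)
    if not 1 <= lig_res <= n:
        raise ParameterError("ligand_residue outside chain")

    atoms: list[Atom] = []
    serial = 1
    cb_coords: dict[int, np.ndarray] = {}
    for r in range(1, n + 1):
        ang = math.radians(HELIX_TWIST * (r - 1))
        z = HELIX_RISE * (r - 1)
        ca = np.array([CA_RADIUS * math.cos(ang), CA_RADIUS * math.sin(ang), z])
        cb = np.array([CB_RADIUS * math.cos(ang), CB_RADIUS * math.sin(ang), z])
        cb_coords[r] = cb
        for name, coord in (("CA", ca), ("CB", cb)):
            atoms.append(
                Atom(serial, name, "C", spec.residue_name, "A", r, tuple(coord), False)
            )
            serial += 1
    direction = cb_coords[lig_res].copy()
    direction[2] = 0.0
    direction /= np.linalg.norm(direction)
    lig_coord = cb_coords[lig_res] + spec.ligand_offset * direction
    atoms.append(
        Atom(serial, "FE", "FE", spec.ligand_name, "L", n + 1, tuple(lig_coord), True)
    )
    return Structure(atoms=atoms)


def write_pdb(s: Structure, path: str) -> None:
    """Minimal fixed-column PDB writer for toy structures."""
    with open(path, "w") as fh:
        for a in s.atoms:
            record = "HETATM" if a.is_ligand else "ATOM  "
            x, y, z = a.coord
            name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
            fh.write(
                f"{record}{a.serial:5d} {name}{'':1s}{a.residue_name:>3s} {a.chain:1s}"
                f"{a.residue_number:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {a.element:>2s}\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# chromatograms


@dataclass
class ChromatogramSpec:
    """Gaussian peaks: (retention time min, m/z, amplitude, sigma min)."""

    peaks: list[tuple[float, float, float, float]] = field(default_factory=list)
    noise_sd: float = 0.0
    t_start: float = 0.0
    t_end: float = 10.0
    scans_per_min: float = 90.0  # 1.5 spectra/s


def make_chromatogram(spec: ChromatogramSpec, seed: int = 0) -> SpectraSeries:
    """Uniform-grid scans; each peak contributes a Gaussian-in-time intensity
    at its m/z; Gaussian noise of ``noise_sd`` added and clipped at 0."""
    for _, _, _, sigma in spec.peaks:
        if sigma <= 0:
            raise ParameterError("peak sigma must be positive")
    if spec.t_end <= spec.t_start or spec.scans_per_min <= 0:
        raise ParameterError("bad time grid")
    rng = np.random.default_rng(seed)
    dt = 1.0 / spec.scans_per_min
    times = np.arange(spec.t_start, spec.t_end + dt / 2, dt)
    mz_list: list[np.ndarray] = []
    inten_list: list[np.ndarray] = []
    peak_mz = np.array([p[1] for p in spec.peaks]) if spec.peaks else np.empty(0)
    for t in times:
        inten = np.array(
            [amp * math.exp(-((t - rt) ** 2) / (2.0 * sigma**2)) for rt, _, amp, sigma in spec.peaks]
        )
        if spec.noise_sd > 0:
            inten = inten + rng.normal(0.0, spec.noise_sd, size=inten.shape)
        mz_list.append(peak_mz.copy())
        inten_list.append(np.clip(inten, 0.0, None))
    return SpectraSeries(times=times, mz=mz_list, intensity=inten_list)
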