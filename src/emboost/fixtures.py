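"""Synthetic paired data for desk-scale testing and benchmarking.

Generates reproducible atom clouds (blob, helix or sheet motifs with
protein-like elements and ≥ 1 Å spacing), builds their ideal
reference-Gaussian maps, and degrades them into experimental-like inputs
by Gaussian blurring, optional B-factor-style Fourier amplitude damping
(exp(-B s²/4)) and additive seeded Gaussian noise with a clamp at zero.

The degradation is a stand-in for experimental map imperfections: it gives
the network a learnable inverse mapping, it does not claim to model cryo-EM
image formation.  Defaults (R0 = 4 Å simulation, 1.5 Å blur, noise at 5% of
peak density, damping off) are fixed study conditions for the test suite.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import gemmi
import numpy as np
from scipy import ndimage

from .grid import VoxelGrid, write_map
from .simulate import gaussian_params_from_resolution, simulate_map
from .structure import AtomicStructure

__all__ = [
    "DegradationParams",
    "random_structure",
    "degrade",
    "make_dataset",
    "load_dataset",
    "write_structure_pdb",
]

DEFAULT_RESOLUTION = 4.0  # Å
DEFAULT_BOX = 64.0  # Å
_ELEMENTS = np.array(["C", "N", "O", "S"])
_ELEMENT_Z = {"C": 6, "N": 7, "O": 8, "S": 16}
_ELEMENT_P = np.array([0.62, 0.17, 0.19, 0.02])
MIN_SPACING = 1.0  # Å


@dataclasses.dataclass(frozen=True)
class DegradationParams:
    """Map degradation: blur (Å), additive noise (fraction of the ideal
    map's peak density), Fourier damping B-factor (Å²), and the noise seed."""

    blur_sigma: float = 1.5
    noise_sigma: float = 0.05
    damping_bfactor: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.blur_sigma < 0 or self.noise_sigma < 0 or self.damping_bfactor < 0:
            raise ValueError("degradation parameters must be nonnegative")


def _motif_positions(n_atoms: int, motif: str, box: float, rng: np.random.Generator) -> np.ndarray:
    margin = 0.12 * box
    lo, hi = margin, box - margin
    center = box / 2.0
    if motif == "blob":
        pts = rng.normal(center, box / 7.0, size=(n_atoms, 3))
    elif motif == "helix":
        # idealized alpha-helix-like spiral: 1.5 Å rise, 100 deg twist, 2.3 Å radius
        i = np.arange(n_atoms)
        theta = np.deg2rad(100.0) * i
        z = 1.5 * i
        z = z - z.mean() + center
        pts = np.stack(
            [center + 2.3 * np.cos(theta), center + 2.3 * np.sin(theta), z], axis=1
        )
        pts += rng.normal(0, 0.25, size=pts.shape)
    elif motif == "sheet":
        # planar grid with strand-like spacing (3.5 Å along, 4.8 Å across)
        per_strand = max(2, int(np.ceil(np.sqrt(n_atoms))))
        i = np.arange(n_atoms)
        row, col = i // per_strand, i % per_strand
        pts = np.stack(
            [col * 3.5, row * 4.8, np.zeros_like(i, dtype=float)], axis=1
        )
        pts -= pts.mean(axis=0)
        pts += center
        pts += rng.normal(0, 0.3, size=pts.shape)
    else:
        raise ValueError(f"unknown motif {motif!r}; use blob, helix or sheet")
    return np.clip(pts, lo, hi)


def random_structure(
    n_atoms: int,
    motif: str = "blob",
    box: float = DEFAULT_BOX,
    seed: int = 0,
) -> AtomicStructure:
    """A reproducible synthetic atom cloud inside ``box`` Å.

    Atoms use protein-like element frequencies (C/N/O/S) and keep at least
    1 Å pairwise spacing; positions violating the spacing are resampled,
    and a box that cannot host ``n_atoms`` at that spacing is an error.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    # sphere-packing style capacity check at minimum spacing
    usable = max(box - 2 * 0.12 * box, 0.0)
    if n_atoms > (usable / MIN_SPACING + 1) ** 3 * 0.5:
        raise ValueError(f"box {box} Å too small for {n_atoms} atoms at {MIN_SPACING} Å spacing")
    rng = np.random.default_rng(np.random.SeedSequence([seed, n_atoms]))
    pts = _motif_positions(n_atoms, motif, box, rng)
    accepted: list[np.ndarray] = []
    for p in pts:
        tries = 0
        while accepted and np.min(
            np.linalg.norm(np.asarray(accepted) - p, axis=1)
        ) < MIN_SPACING:
            p = _motif_positions(1, "blob", box, rng)[0]
            tries += 1
            if tries > 2000:
                raise ValueError(
                    f"cannot place {n_atoms} atoms in a {box} Å box at {MIN_SPACING} Å spacing"
                )
        accepted.append(p)
    coords = np.asarray(accepted)
    elements = rng.choice(_ELEMENTS, size=n_atoms, p=_ELEMENT_P)
    numbers = [_ELEMENT_Z[e] for e in elements]
    chains = np.full(n_atoms, "A", dtype=object)
    return AtomicStructure(elements, numbers, coords, chains)


def degrade(ideal: VoxelGrid, p: DegradationParams) -> VoxelGrid:
    """Blur + Fourier damping + additive noise + clamp at zero."""
    data = ideal.data.astype(np.float64)
    vx, vy, vz = ideal.voxel_size
    if p.blur_sigma > 0:
        data = ndimage.gaussian_filter(
            data, sigma=(p.blur_sigma / vz, p.blur_sigma / vy, p.blur_sigma / vx)
        )
    if p.damping_bfactor > 0:
        nz, ny, nx = data.shape
        fx = np.fft.fftfreq(nx, d=vx)
        fy = np.fft.fftfreq(ny, d=vy)
        fz = np.fft.fftfreq(nz, d=vz)
        s2 = fz[:, None, None] ** 2 + fy[None, :, None] ** 2 + fx[None, None, :] ** 2
        data = np.fft.ifftn(np.fft.fftn(data) * np.exp(-p.damping_bfactor * s2 / 4.0)).real
    if p.noise_sigma > 0:
        rng = np.random.default_rng(np.random.SeedSequence([p.seed, 0xD1CE]))
        peak = float(ideal.data.max())
        data = data + rng.normal(0.0, p.noise_sigma * peak, size=data.shape)
    data = np.clip(data, 0.0, None)
    return ideal.with_data(data.astype(np.float32))


def write_structure_pdb(s: AtomicStructure, path: str | Path) -> None:
    """Persist a synthetic atom cloud as a minimal PDB (one atom per residue)."""
    st = gemmi.Structure()
    st.name = "synthetic"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    counters: dict[str, int] = {}
    for el, (x, y, z), ch in zip(s.elements, s.coords, s.chains):
        ch = str(ch)
        if ch not in chains:
            chains[ch] = gemmi.Chain(ch)
            counters[ch] = 0
        counters[ch] += 1
        res = gemmi.Residue()
        res.name = "UNK"
        res.seqid = gemmi.SeqId(counters[ch], " ")
        res.het_flag = "H"
        atom = gemmi.Atom()
        atom.name = str(el)
        atom.element = gemmi.Element(str(el))
        atom.pos = gemmi.Position(float(x), float(y), float(z))
        atom.occ = 1.0
        res.add_atom(atom)
        chains[ch].add_residue(res)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def make_dataset(
    out_dir: str | Path,
    n_maps: int,
    sim_resolution: float = DEFAULT_RESOLUTION,
    degradation: DegradationParams | None = None,
    box: float = DEFAULT_BOX,
    n_atoms: int = 150,
    seed: int = 0,
    force: bool = False,
) -> dict:
    """Write ``n_maps`` (input, target, structure) triples plus a manifest.

    Each map gets its own structure (motifs cycle blob/helix/sheet), an
    ideal map simulated at ``sim_resolution`` on a 1 Å grid, and a degraded
    input.  Every parameter and derived seed is recorded in manifest.json,
    so regenerating with the same arguments is byte-identical.
    """
    if n_maps < 1:
        raise ValueError("n_maps must be >= 1")
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(f"{out_dir} exists and is not empty (use force=True)")
    out_dir.mkdir(parents=True, exist_ok=True)
    degradation = degradation or DegradationParams()
    params = gaussian_params_from_resolution(sim_resolution)
    n_vox = int(round(box))
    template = VoxelGrid(np.zeros((n_vox, n_vox, n_vox), dtype=np.float32))

    motifs = ["blob", "helix", "sheet"]
    entries = []
    for i in range(n_maps):
        map_seed = int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31))
        motif = motifs[i % len(motifs)]
        s = random_structure(n_atoms, motif=motif, box=box, seed=map_seed)
        ideal = simulate_map(s, params, template)
        deg = degrade(ideal, dataclasses.replace(degradation, seed=map_seed))
        stem = f"{i:03d}"
        write_map(deg, out_dir / f"input_{stem}.mrc")
        write_map(ideal, out_dir / f"target_{stem}.mrc")
        write_structure_pdb(s, out_dir / f"structure_{stem}.pdb")
        entries.append(
            {
                "index": i,
                "motif": motif,
                "seed": map_seed,
                "n_atoms": n_atoms,
                "input": f"input_{stem}.mrc",
                "target": f"target_{stem}.mrc",
                "structure": f"structure_{stem}.pdb",
            }
        )
    manifest = {
        "n_maps": n_maps,
        "sim_resolution": sim_resolution,
        "box": box,
        "n_atoms": n_atoms,
        "seed": seed,
        "degradation": dataclasses.asdict(degradation),
        "entries": entries,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def load_dataset(path: str | Path) -> dict:
    path = Path(path)
    with open(path / "manifest.json") as fh:
        manifest = json.load(fh)
    manifest["root"] = str(path)
    return manifest
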