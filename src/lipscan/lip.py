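"""Detection of LIPs: light interfaces of high polarity.

The method scans each chain with a sliding probe of eight contiguous solved
residues.  For every window position the probe is treated as one side of an
interface and the rest of the chain (intra mode) or an entire partner chain
(inter mode) as the other.  Two window statistics are recorded at the probe's
fourth residue:

* PR, the polarity ratio — buried polar surface over buried apolar surface at
  the probe/environment interface (buried area per atom is the SASA the atom
  loses on complexation);
* ρ, the packing density — standard over actual Voronoi volumes of the
  interface atoms.

An mLIP is a PR peak above 0.8 extended over adjacent residues with PR above
the 0.5 baseline, kept only if at least one of its residues has ρ below the
profile mean minus one standard deviation.  Cropping the mLIP out of the
structure and collecting the residues whose SASA rises by more than 1.0 Å²
yields its cLIP; mLIP plus cLIP form the full LIP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import packing
from .config import StandardVolumeTable, load_standard_volumes
from .structure import Chain, Residue, ResidueKey, Structure, crop
from .surface import atom_sasa, canonical_frame, delta_sasa, sasa_of_coords

__all__ = [
    "DetectionParams",
    "InterfacePatch",
    "ProfilePoint",
    "LipProfile",
    "MLip",
    "CLip",
    "Lip",
    "LipAnalysis",
    "interface_patch",
    "polarity_ratio",
    "scan_profile",
    "detect_mlips",
    "compute_clip",
    "find_lips",
]

PR_INFINITY = 1.0e6  # finite stand-in for an all-polar buried interface


@dataclass(frozen=True)
class DetectionParams:
    """Detection thresholds; defaults are the published operating point."""

    window: int = 8                 # probe length, residues
    pr_peak: float = 0.8            # minimum PR at a peak
    pr_base: float = 0.5            # PR baseline for peak extension
    rho_sd_factor: float = 1.0      # require ρ < mean − factor·sd somewhere
    dsasa_cutoff: float = 1.0       # Å², strict > for cLIP membership
    interface_cutoff: float = 0.1   # Å² buried area for interface membership
    probe_radius: float = 1.4       # Å, solvent probe
    n_points: int = 960             # SASA sphere points


@dataclass
class InterfacePatch:
    probe_keys: list[ResidueKey]
    environment_keys: list[ResidueKey]
    # parallel arrays over the interface atoms (buried area > cutoff)
    atom_ids: list[int]             # indices into the context structure's atoms()
    buried: np.ndarray              # Å² per interface atom
    polar: np.ndarray               # bool per interface atom
    buried_polar: float = 0.0
    buried_apolar: float = 0.0


@dataclass
class ProfilePoint:
    residue_key: ResidueKey
    pr: float | None = None
    rho: float | None = None

    @property
    def defined(self) -> bool:
        return self.pr is not None or self.rho is not None


@dataclass
class LipProfile:
    chain_id: str
    mode: str                       # "intra" | "inter"
    partner: str | None
    points: list[ProfilePoint]
    rho_mean: float | None = None
    rho_sd: float | None = None

    def point(self, key: ResidueKey) -> ProfilePoint | None:
        for p in self.points:
            if p.residue_key == key:
                return p
        return None


@dataclass
class MLip:
    chain_id: str
    span: list[ResidueKey]          # contiguous, sequence order
    mode: str
    partner: str | None
    peak_pr: float


@dataclass
class CLip:
    parent: MLip
    members: list[tuple[ResidueKey, float]]  # (residue, ΔSASA Å²), ΔSASA > cutoff

    @property
    def member_keys(self) -> list[ResidueKey]:
        return [k for k, _ in self.members]


@dataclass
class Lip:
    mlip: MLip
    clip: CLip

    @property
    def residue_set(self) -> set[ResidueKey]:
        """Full-LIP residues; each residue counted once."""
        return set(self.mlip.span) | set(self.clip.member_keys)


@dataclass
class LipAnalysis:
    structure: Structure
    profiles: list[LipProfile] = field(default_factory=list)
    lips: list[Lip] = field(default_factory=list)
    params: DetectionParams = field(default_factory=DetectionParams)


# ---------------------------------------------------------------------------
# context bookkeeping

class _Context:
    """Atom bookkeeping for one (chain | chain-pair) analysis structure."""

    def __init__(self, structure: Structure, params: DetectionParams,
                 volumes: StandardVolumeTable | None = None):
        self.structure = structure
        self.params = params
        atoms = structure.atoms()
        raw = np.array([a.coords for a in atoms])
        # canonical principal-axes frame: results do not depend on how the
        # input file happens to be oriented, and rigid copies (homodimer
        # subunits) give identical profiles
        self.frame = canonical_frame(raw)
        rot, cen = self.frame
        self.coords = (raw - cen) @ rot
        self.radii = np.array([a.radius for a in atoms], dtype=float)
        self.polar = np.array([a.polarity == "polar" for a in atoms])
        self.index_of = {id(a): i for i, a in enumerate(atoms)}
        volumes = volumes or load_standard_volumes()
        self.std_volumes = np.array([
            packing.standard_volume(r.name, a.name, a.element, volumes)
            for r in structure.residues() for a in r.atoms
        ])
        self._cells = None

    @property
    def cells(self):
        if self._cells is None:
            cells = packing.voronoi_cells_of_coords(self.coords)
            self._cells = {c.atom_index: c for c in cells}
        return self._cells

    def atom_ids(self, residues: list[Residue]) -> list[int]:
        return [self.index_of[id(a)] for r in residues for a in r.atoms]

    def sasa(self, ids: list[int]) -> np.ndarray:
        return sasa_of_coords(self.coords[ids], self.radii[ids],
                              probe=self.params.probe_radius,
                              n_points=self.params.n_points)


def _subset_structure(structure: Structure, chain_ids: list[str]) -> Structure:
    return Structure(chains=[structure.chain(c) for c in chain_ids],
                     het_residues=structure.het_residues,
                     site_annotations=structure.site_annotations,
                     provenance=structure.provenance)


# ---------------------------------------------------------------------------
# interface patches and PR

def interface_patch(probe: list[Residue], environment: list[Residue],
                    context: _Context) -> InterfacePatch:
    """Buried-area bookkeeping for the probe-vs-environment interface.

    Per atom (both sides), buried area b = SASA(own component isolated) −
    SASA(probe ∪ environment); atoms with b above the interface cutoff form
    the interface.
    """
    if not probe or not environment:
        raise ValueError("probe and environment must be non-empty")
    probe_keys = {r.key for r in probe}
    if probe_keys & {r.key for r in environment}:
        raise ValueError("probe and environment overlap")

    probe_ids = context.atom_ids(probe)
    env_ids = context.atom_ids(environment)
    both = probe_ids + env_ids

    sasa_probe = context.sasa(probe_ids)
    sasa_env = context.sasa(env_ids)
    sasa_complex = context.sasa(both)
    isolated = np.concatenate([sasa_probe, sasa_env])
    buried = isolated - sasa_complex

    mask = buried > context.params.interface_cutoff
    ids = [both[i] for i in np.nonzero(mask)[0]]
    b = buried[mask]
    polar = context.polar[ids]
    return InterfacePatch(
        probe_keys=[r.key for r in probe],
        environment_keys=[r.key for r in environment],
        atom_ids=ids, buried=b, polar=polar,
        buried_polar=float(b[polar].sum()),
        buried_apolar=float(b[~polar].sum()),
    )


def polarity_ratio(patch: InterfacePatch) -> float | None:
    """PR = buried polar / buried apolar area; None when the interface is empty."""
    if len(patch.atom_ids) == 0:
        return None
    if patch.buried_apolar <= 0.0:
        return PR_INFINITY if patch.buried_polar > 0.0 else None
    return patch.buried_polar / patch.buried_apolar


def _patch_rho(patch: InterfacePatch, context: _Context) -> float | None:
    if len(patch.atom_ids) == 0:
        return None
    std = {i: float(context.std_volumes[i]) for i in patch.atom_ids}
    return packing.packing_density(patch.atom_ids, context.cells, std)


# ---------------------------------------------------------------------------
# profile scan

def scan_profile(structure: Structure, chain_id: str, mode: str,
                 partner: str | None = None,
                 params: DetectionParams | None = None,
                 context: _Context | None = None) -> LipProfile:
    """Slide the 8-residue probe along a chain and record (PR, ρ) per position.

    ``mode="intra"``: the environment is the same chain minus the probe;
    ``mode="inter"``: the environment is the entire partner chain.  Windows
    require eight consecutively solved (peptide-bonded) residues, so profiles
    are discontinuous at structural gaps; the window value is assigned to the
    probe's fourth residue.
    """
    params = params or DetectionParams()
    if mode not in ("intra", "inter"):
        raise ValueError("mode must be 'intra' or 'inter'")
    if mode == "inter" and (partner is None or partner == chain_id):
        raise ValueError("inter mode needs a distinct partner chain")

    if context is None:
        ids = [chain_id] if mode == "intra" else [chain_id, partner]
        context = _Context(_subset_structure(structure, ids), params)

    chain = structure.chain(chain_id)
    segments = structure.segments(chain_id)
    w = params.window
    mid = w // 2 - 1  # 0-based offset of the probe's fourth residue

    values: dict[ResidueKey, tuple[float | None, float | None]] = {}
    if len(chain.residues) < w:
        import warnings
        warnings.warn(f"chain {chain_id}: fewer than {w} solved residues; empty profile")
    for seg in segments:
        for start in range(0, len(seg) - w + 1):
            probe = seg[start:start + w]
            if mode == "intra":
                probe_keys = {r.key for r in probe}
                environment = [r for r in chain.residues if r.key not in probe_keys]
            else:
                environment = structure.chain(partner).residues
            if not environment:
                continue
            patch = interface_patch(probe, environment, context)
            pr = polarity_ratio(patch)
            rho = _patch_rho(patch, context)
            values[probe[mid].key] = (pr, rho)

    points = [ProfilePoint(residue_key=r.key, pr=values.get(r.key, (None, None))[0],
                           rho=values.get(r.key, (None, None))[1])
              for r in chain.residues]
    rhos = [p.rho for p in points if p.rho is not None]
    profile = LipProfile(chain_id=chain_id, mode=mode, partner=partner, points=points)
    if rhos:
        profile.rho_mean = float(np.mean(rhos))
        profile.rho_sd = float(np.std(rhos))
    return profile


def detect_mlips(profile: LipProfile, params: DetectionParams | None = None,
                 chain_adjacency: dict[ResidueKey, ResidueKey] | None = None,
                 ) -> list[MLip]:
    """Apply the threshold rules to a profile.

    1. local PR maxima above the peak cut-off; 2. extension over contiguous
    defined points while PR stays above the baseline; 3. merge of overlapping
    candidate regions; 4. at least one region residue with
    ρ < mean − ``rho_sd_factor``·sd.
    """
    params = params or DetectionParams()
    pts = profile.points
    n = len(pts)

    def pr(i: int) -> float | None:
        return pts[i].pr

    # contiguous runs of points with defined PR
    runs: list[list[int]] = []
    for i, p in enumerate(pts):
        if p.pr is None:
            continue
        if runs and runs[-1][-1] == i - 1:
            runs[-1].append(i)
        else:
            runs.append([i])

    candidates: list[tuple[int, int, float]] = []  # (start, end inclusive, peak)
    for run in runs:
        for i in run:
            left = pr(i - 1) if i - 1 in run else None
            right = pr(i + 1) if i + 1 in run else None
            if pr(i) <= params.pr_peak:
                continue
            if (left is not None and left > pr(i)) or \
               (right is not None and right > pr(i)):
                continue
            lo = i
            while lo - 1 in run and pr(lo - 1) > params.pr_base:
                lo -= 1
            hi = i
            while hi + 1 in run and pr(hi + 1) > params.pr_base:
                hi += 1
            candidates.append((lo, hi, pr(i)))

    # merge overlapping candidate regions
    candidates.sort()
    merged: list[list[float]] = []
    for lo, hi, peak in candidates:
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
            merged[-1][2] = max(merged[-1][2], peak)
        else:
            merged.append([lo, hi, peak])

    if profile.rho_mean is None or profile.rho_sd is None:
        return []
    rho_cut = profile.rho_mean - params.rho_sd_factor * profile.rho_sd

    mlips = []
    for lo, hi, peak in merged:
        region = pts[int(lo):int(hi) + 1]
        if not any(p.rho is not None and p.rho < rho_cut for p in region):
            continue
        mlips.append(MLip(chain_id=profile.chain_id,
                          span=[p.residue_key for p in region],
                          mode=profile.mode, partner=profile.partner,
                          peak_pr=float(peak)))
    return mlips


def compute_clip(context_structure: Structure, mlip: MLip,
                 params: DetectionParams | None = None) -> CLip:
    """Crop the mLIP span and collect residues gaining more than 1.0 Å² SASA.

    ``context_structure`` is the chain for intra mode or the chain pair for
    inter mode; the cLIP may contain residues from either chain.
    """
    params = params or DetectionParams()
    # one shared canonical frame for both runs keeps per-atom quadrature
    # strictly comparable (ΔSASA exactly ≥ 0 for retained residues)
    frame = canonical_frame(context_structure.coords())
    full = atom_sasa(context_structure, probe=params.probe_radius,
                     n_points=params.n_points, frame=frame)
    retained, _removed = crop(context_structure, set(mlip.span))
    cropped = atom_sasa(retained, probe=params.probe_radius,
                        n_points=params.n_points, frame=frame)
    members = clip_members(delta_sasa(full, cropped), params.dsasa_cutoff)
    members.sort(key=lambda kv: _key_order(context_structure, kv[0]))
    return CLip(parent=mlip, members=members)


def clip_members(records, cutoff: float = 1.0) -> list[tuple[ResidueKey, float]]:
    """cLIP membership rule: ΔSASA strictly greater than the cutoff."""
    return [(rec.residue_key, rec.delta) for rec in records if rec.delta > cutoff]


def _key_order(structure: Structure, key: ResidueKey) -> tuple:
    for ci, chain in enumerate(structure.chains):
        for ri, r in enumerate(chain.residues):
            if r.key == key:
                return (ci, ri)
    return (len(structure.chains), 0)


def find_lips(structure: Structure, mode: str = "both",
              chains: list[str] | None = None,
              params: DetectionParams | None = None) -> LipAnalysis:
    """Full analysis: intra profiles per chain, inter profiles per ordered pair.

    For a dimer in ``mode="both"`` this is the standard four-calculation set
    (intra-A, intra-B, inter-A:B, inter-B:A).  For larger oligomers pass the
    chain pair to analyse via ``chains``.
    """
    params = params or DetectionParams()
    if mode not in ("intra", "inter", "both"):
        raise ValueError("mode must be intra, inter or both")
    chains = chains or structure.chain_ids
    unknown = set(chains) - set(structure.chain_ids)
    if unknown:
        raise KeyError(f"unknown chains: {sorted(unknown)}")
    if mode in ("inter", "both") and len(chains) < 2 and mode == "inter":
        raise ValueError("inter mode requires at least two chains")

    analysis = LipAnalysis(structure=structure, params=params)

    if mode in ("intra", "both"):
        for cid in chains:
            sub = _subset_structure(structure, [cid])
            ctx = _Context(sub, params)
            profile = scan_profile(structure, cid, "intra", params=params, context=ctx)
            analysis.profiles.append(profile)
            for mlip in detect_mlips(profile, params):
                clip = compute_clip(sub, mlip, params)
                analysis.lips.append(Lip(mlip=mlip, clip=clip))

    if mode in ("inter", "both") and len(chains) >= 2:
        pairs = [(chains[0], chains[1]), (chains[1], chains[0])]
        for cid, partner in pairs:
            sub = _subset_structure(structure, [cid, partner])
            ctx = _Context(sub, params)
            profile = scan_profile(structure, cid, "inter", partner=partner,
                                   params=params, context=ctx)
            analysis.profiles.append(profile)
            for mlip in detect_mlips(profile, params):
                clip = compute_clip(sub, mlip, params)
                analysis.lips.append(Lip(mlip=mlip, clip=clip))
    return analysis
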