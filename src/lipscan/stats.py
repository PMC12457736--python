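"""Statistical battery for LIP annotation studies.

Amino-acid enrichment factors between LIP and non-LIP regions, two-proportion
Z-tests for SITE enrichment, exposure profiling, and inside/outside
mean-difference analysis of external per-residue scores (conservation,
stability) with Student's t, point-biserial correlation and Cohen's d.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats as sps

from .structure import SiteAnnotation, Structure
from .surface import ExposureClass

__all__ = [
    "RESIDUE_GROUPS",
    "EnrichmentTable",
    "ScoreTable",
    "MeanDifferenceReport",
    "ExposureProfile",
    "SiteLipReport",
    "enrichment_factor",
    "proportion_ztest",
    "mean_difference",
    "site_lip_report",
    "exposure_profile",
    "read_score_table",
    "read_dssp_masks",
]

AA1 = "ACDEFGHIKLMNPQRSTVWY"

# Polarity groups partitioning the 20 canonical amino acids.
RESIDUE_GROUPS = {
    "non-polar": set("AGVLIPMCFW"),
    "polar-uncharged": set("YSTNQ"),
    "negative": set("DE"),
    "positive": set("KRH"),
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


@dataclass
class EnrichmentEntry:
    count_in: int
    count_out: int
    nu_in: float
    nu_out: float
    ef: float | None          # None (flagged) when nu_out == 0
    se: float | None          # standard error of EF by binomial propagation


@dataclass
class EnrichmentTable:
    per_aa: dict[str, EnrichmentEntry]
    per_group: dict[str, EnrichmentEntry]
    n_in: int
    n_out: int


def enrichment_factor(in_counts: dict[str, int], out_counts: dict[str, int],
                      ) -> EnrichmentTable:
    """EF = ν(in-region)/ν(out-region) per amino acid and per polarity group.

    ν is the relative frequency within the region; group frequencies are sums
    of member frequencies.  Standard errors follow binomial propagation on
    both frequencies.  EF is flagged undefined (None) where ν_out = 0.
    """
    bad = (set(in_counts) | set(out_counts)) - set(AA1)
    if bad:
        raise ValueError(f"non-canonical amino acids in counts: {sorted(bad)}")
    n_in = sum(in_counts.values())
    n_out = sum(out_counts.values())
    if n_in <= 0 or n_out <= 0:
        raise ValueError("both regions need a positive residue total")

    def entry(k_in: int, k_out: int) -> EnrichmentEntry:
        nu_in = k_in / n_in
        nu_out = k_out / n_out
        if nu_out == 0:
            return EnrichmentEntry(k_in, k_out, nu_in, nu_out, None, None)
        ef = nu_in / nu_out
        se = None
        if nu_in > 0:
            var_in = nu_in * (1 - nu_in) / n_in
            var_out = nu_out * (1 - nu_out) / n_out
            se = ef * math.sqrt(var_in / nu_in ** 2 + var_out / nu_out ** 2)
        return EnrichmentEntry(k_in, k_out, nu_in, nu_out, ef, se)

    per_aa = {aa: entry(in_counts.get(aa, 0), out_counts.get(aa, 0)) for aa in AA1}
    per_group = {
        name: entry(sum(in_counts.get(aa, 0) for aa in members),
                    sum(out_counts.get(aa, 0) for aa in members))
        for name, members in RESIDUE_GROUPS.items()
    }
    return EnrichmentTable(per_aa=per_aa, per_group=per_group, n_in=n_in, n_out=n_out)


def proportion_ztest(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion Z-test, two-tailed.

    Returns (z, p) for H0: k1/n1 == k2/n2.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0.0:
        return 0.0, 1.0
    z = (p1 - p2) / se
    p = 2.0 * sps.norm.sf(abs(z))
    return z, p


@dataclass
class ScoreTable:
    """Per-residue scores keyed by (chain, resnum, icode)."""

    scores: dict[tuple[str, int, str], float]
    sign_convention: str = ""  # e.g. "positive = destabilizing"

    def values_for(self, keys) -> np.ndarray:
        return np.array([self.scores[k] for k in keys if k in self.scores])


def read_score_table(path: str | Path, sign_convention: str = "") -> ScoreTable:
    """Read a TSV with columns chain, resnum, icode, score ('-' or '' icode)."""
    scores = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if parts[0].lower() in ("chain",):  # header
            continue
        if len(parts) < 4:
            raise ValueError(f"{path}:{ln}: expected chain, resnum, icode, score")
        chain, resnum, icode, score = parts[0], int(parts[1]), parts[2], float(parts[3])
        icode = "" if icode in ("-", ".", "") else icode
        scores[(chain, resnum, icode)] = score
    return ScoreTable(scores=scores, sign_convention=sign_convention)


@dataclass
class MeanDifferenceReport:
    element: str
    mean_in: float
    mean_out: float
    t: float
    p: float
    point_biserial: float
    cohens_d: float
    n_in: int
    n_out: int

    @property
    def difference(self) -> float:
        """mean(inside element) − mean(outside element)."""
        return self.mean_in - self.mean_out


def mean_difference(scores: ScoreTable, element_mask, element: str = "",
                    equal_var: bool = True) -> MeanDifferenceReport:
    """Inside-vs-outside mean difference with t, point-biserial r and Cohen's d.

    ``element_mask`` is the set of residue keys belonging to the structure
    element; all other scored residues form the outside group.  The t-test is
    pooled-variance Student by default (``equal_var=False`` gives Welch).
    The point-biserial r is derived from t (r² = t²/(t²+df)), signed like the
    mean difference.
    """
    mask = set(element_mask)
    missing = mask - set(scores.scores)
    if missing:
        warnings.warn(f"{len(missing)} masked residues have no score; ignored")
        mask -= missing
    inside = np.array([v for k, v in scores.scores.items() if k in mask])
    outside = np.array([v for k, v in scores.scores.items() if k not in mask])
    if len(inside) == 0 or len(outside) == 0:
        raise ValueError("both inside and outside groups must be non-empty")

    t, p = sps.ttest_ind(inside, outside, equal_var=equal_var)
    n1, n2 = len(inside), len(outside)
    df = n1 + n2 - 2
    r = float(t) / math.sqrt(float(t) ** 2 + df) if df > 0 else float("nan")
    pooled_sd = math.sqrt(((n1 - 1) * inside.var(ddof=1) +
                           (n2 - 1) * outside.var(ddof=1)) / df) if df > 0 else float("nan")
    d = (inside.mean() - outside.mean()) / pooled_sd if pooled_sd > 0 else 0.0
    return MeanDifferenceReport(
        element=element, mean_in=float(inside.mean()), mean_out=float(outside.mean()),
        t=float(t), p=float(p), point_biserial=r, cohens_d=float(d),
        n_in=n1, n_out=n2,
    )


@dataclass
class SiteLipRow:
    element: str
    count_site: int
    pct_site: float
    count_all: int
    pct_all: float
    z: float
    p: float


@dataclass
class SiteLipReport:
    rows: list[SiteLipRow]
    n_site: int
    n_all: int
    skipped_members: list = field(default_factory=list)


def site_lip_report(lips, sites: list[SiteAnnotation], structure: Structure,
                    ) -> SiteLipReport:
    """Proportion of residues in mLIPs / cLIPs / full LIPs / no LIP,
    for SITE-annotated residues and for all residues of the structure,
    with a two-proportion Z-test per row.

    Full-LIP membership counts each residue once even when it belongs to both
    an mLIP and a cLIP.
    """
    all_keys = set(structure.residue_keys())
    mlip_keys: set = set()
    clip_keys: set = set()
    for lip in lips:
        mlip_keys |= set(lip.mlip.span)
        clip_keys |= set(lip.clip.member_keys)
    full_keys = mlip_keys | clip_keys

    site_keys: set = set()
    skipped = []
    for ann in sites:
        for (cid, num, icode, resname, _is_protein) in ann.members:
            key = (cid, num, icode)
            if key in all_keys:
                site_keys.add(key)
            else:
                skipped.append((ann.site_id, key, resname))
                warnings.warn(f"SITE {ann.site_id} member {key} ({resname}) "
                              f"not a protein residue of the structure; skipped")

    n_site, n_all = len(site_keys), len(all_keys)
    rows = []
    for name, keys in (("mLIPs", mlip_keys), ("cLIPs", clip_keys),
                       ("Full LIPs", full_keys), ("NO LIPs", all_keys - full_keys)):
        k_site = len(keys & site_keys)
        k_all = len(keys & all_keys)
        if n_site > 0:
            z, p = proportion_ztest(k_site, n_site, k_all, n_all)
            pct_site = 100.0 * k_site / n_site
        else:
            z, p, pct_site = float("nan"), float("nan"), float("nan")
        rows.append(SiteLipRow(element=name, count_site=k_site, pct_site=pct_site,
                               count_all=k_all, pct_all=100.0 * k_all / n_all,
                               z=z, p=p))
    return SiteLipReport(rows=rows, n_site=n_site, n_all=n_all,
                         skipped_members=skipped)


@dataclass
class ExposureProfileRow:
    element: str
    counts: dict[str, int]        # buried / intermediate / exposed
    percentages: dict[str, float]
    total: int                    # all residues in the element, incl. undefined
    n_undefined: int


@dataclass
class ExposureProfile:
    rows: list[ExposureProfileRow]


def exposure_profile(residue_sets: dict[str, set],
                     exposures: dict[tuple, ExposureClass]) -> ExposureProfile:
    """Buried/intermediate/exposed split per named residue set.

    Residues with undefined exposure (non-canonical) stay in the total but are
    excluded from the class counts, so counts may sum to less than the total.
    Percentages use the element total as denominator.
    """
    rows = []
    for name, keys in residue_sets.items():
        counts = {"buried": 0, "intermediate": 0, "exposed": 0}
        undefined = 0
        for key in keys:
            exp = exposures.get(key)
            if exp is None or exp.label is None:
                undefined += 1
            else:
                counts[exp.label] += 1
        total = len(keys)
        pct = {k: (100.0 * v / total if total else float("nan"))
               for k, v in counts.items()}
        rows.append(ExposureProfileRow(element=name, counts=counts,
                                       percentages=pct, total=total,
                                       n_undefined=undefined))
    return ExposureProfile(rows=rows)


def read_dssp_masks(path: str | Path) -> dict[str, set]:
    """Secondary-structure masks from a standard DSSP output file.

    alpha = 'H' only (3₁₀ and π helices excluded); beta = 'B' or 'E';
    coil = blank assignment (turns and bends excluded).  Returns residue-key
    sets keyed by 'alpha', 'beta', 'coil'.
    """
    from Bio.PDB.DSSP import make_dssp_dict

    dssp, _keys = make_dssp_dict(str(path))
    masks = {"alpha": set(), "beta": set(), "coil": set()}
    for (chain_id, res_id), record in dssp.items():
        het, resnum, icode = res_id
        key = (chain_id, int(resnum), (icode or "").strip())
        ss = record[1]
        if ss == "H":
            masks["alpha"].add(key)
        elif ss in ("B", "E"):
            masks["beta"].add(key)
        elif ss in (" ", "-", ""):
            masks["coil"].add(key)
    return masks
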