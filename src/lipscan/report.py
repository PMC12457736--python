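"""Run artifacts: profile TSVs, LIP reports, dual-profile plots, summary text."""

from __future__ import annotations

import json
from pathlib import Path

from .lip import DetectionParams, LipAnalysis, LipProfile
from .structure import Structure

__all__ = ["profile_tsv", "lip_report_dict", "summary_text", "plot_profile",
           "sasa_tsv", "write_bundle"]

_FLOAT_FMT = "{:.12g}"


def _fmt(value) -> str:
    if value is None:
        return "NA"
    return _FLOAT_FMT.format(value)


def profile_tsv(profile: LipProfile, structure: Structure,
                mlip_keys: set | None = None) -> str:
    """TSV serialization of one profile: chain, mode, partner, resnum, icode,
    resname, PR, rho, in_mlip."""
    mlip_keys = mlip_keys or set()
    lines = ["chain\tmode\tpartner\tresnum\ticode\tresname\tPR\trho\tin_mlip"]
    chain = structure.chain(profile.chain_id)
    names = {r.key: r.name for r in chain.residues}
    for p in profile.points:
        cid, num, icode = p.residue_key
        lines.append("\t".join([
            cid, profile.mode, profile.partner or "-", str(num), icode or "-",
            names.get(p.residue_key, "???"), _fmt(p.pr), _fmt(p.rho),
            "1" if p.residue_key in mlip_keys else "0",
        ]))
    return "\n".join(lines) + "\n"


def sasa_tsv(structure: Structure, sasa, exposures=None) -> str:
    """Per-residue SASA dump with polar/apolar split and exposure class."""
    from .surface import classify_exposure, relative_exposure

    lines = ["chain\tresnum\ticode\tresname\tsasa_total\tsasa_polar\tsasa_apolar"
             "\trel_exposure\tclass"]
    idx = 0
    for res in structure.residues():
        areas = sasa.per_atom_list[idx:idx + len(res.atoms)]
        idx += len(res.atoms)
        polar = sum(a for a, at in zip(areas, res.atoms) if at.polarity == "polar")
        apolar = sum(a for a, at in zip(areas, res.atoms) if at.polarity != "polar")
        rel = relative_exposure(res, sasa.per_residue[res.key])
        lines.append("\t".join([
            res.chain_id, str(res.seq_num), res.icode or "-", res.name,
            _fmt(sasa.per_residue[res.key]), _fmt(polar), _fmt(apolar),
            _fmt(rel), classify_exposure(rel) or "NA",
        ]))
    return "\n".join(lines) + "\n"


def lip_report_dict(analysis: LipAnalysis) -> dict:
    """JSON-serializable report of every detected LIP."""
    out = {"params": vars(analysis.params), "lips": []}
    for lip in analysis.lips:
        m = lip.mlip
        out["lips"].append({
            "chain": m.chain_id,
            "mode": m.mode,
            "partner": m.partner,
            "span": [[c, n, i] for (c, n, i) in m.span],
            "span_label": _span_label(m.span),
            "peak_pr": m.peak_pr,
            "clip": [{"chain": c, "resnum": n, "icode": i, "delta_sasa": d}
                     for (c, n, i), d in lip.clip.members],
            "full_lip_size": len(lip.residue_set),
        })
    return out


def _span_label(span) -> str:
    c0, n0, i0 = span[0]
    c1, n1, i1 = span[-1]
    return f"{c0}:{n0}{i0}-{n1}{i1}"


def summary_text(analysis: LipAnalysis) -> str:
    """Human-readable run summary: mLIP spans, cLIP members, gaps, SITEs."""
    st = analysis.structure
    lines = ["LIP analysis summary", "====================", ""]
    lines.append(f"Structure: {st.provenance or '(in-memory)'}")
    lines.append(f"Chains: {', '.join(st.chain_ids)}"
                 f" ({sum(len(c) for c in st.chains)} residues)")
    p = analysis.params
    lines.append(f"Parameters: window={p.window} pr_peak={p.pr_peak} "
                 f"pr_base={p.pr_base} rho_rule=mean-{p.rho_sd_factor}*sd "
                 f"dsasa={p.dsasa_cutoff} probe={p.probe_radius} "
                 f"n_points={p.n_points} interface_cutoff={p.interface_cutoff}")
    lines.append("")

    if analysis.lips:
        lines.append(f"Detected LIPs: {len(analysis.lips)}")
        for i, lip in enumerate(analysis.lips, 1):
            m = lip.mlip
            tag = f"{m.mode}" + (f" vs {m.partner}" if m.partner else "")
            lines.append(f"  LIP {i}: mLIP {_span_label(m.span)} ({tag}), "
                         f"peak PR {m.peak_pr:.3g}")
            if lip.clip.members:
                members = ", ".join(f"{c}:{n}{i or ''} ({d:.2f} A^2)"
                                    for (c, n, i), d in lip.clip.members)
                lines.append(f"         cLIP: {members}")
            else:
                lines.append("         cLIP: (empty)")
    else:
        lines.append("Detected LIPs: none")
    lines.append("")

    seq_map = st.sequence_map()
    gap_lines = []
    for cid, entries in seq_map.items():
        for e in entries:
            if e["structural_gap"]:
                gap_lines.append(f"  chain {cid}: structural gap between "
                                 f"{e['from'][1]} and {e['to'][1]}")
            elif e["numbering_gap"]:
                gap_lines.append(f"  chain {cid}: numbering jump between "
                                 f"{e['from'][1]} and {e['to'][1]} (no structural break)")
    lines.append("Gaps:")
    lines.extend(gap_lines or ["  none"])
    lines.append("")

    lines.append("SITE annotations:")
    if st.site_annotations:
        for ann in st.site_annotations:
            members = ", ".join(f"{r}{'' if prot else '*'} {c}:{n}{i or ''}"
                                for (c, n, i, r, prot) in ann.members)
            lines.append(f"  {ann.site_id}: {members}")
        if any(not prot for ann in st.site_annotations
               for (*_k, prot) in ann.members):
            lines.append("  (* = non-protein member)")
    else:
        lines.append("  none")
    return "\n".join(lines) + "\n"


def plot_profile(profile: LipProfile, mlips, params: DetectionParams,
                 path: str | Path) -> None:
    """Dual profile plot: PR on top (0.8/0.5 dashed), ρ below (mean−sd dashed),
    mLIP spans shaded."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs = list(range(len(profile.points)))
    labels = [p.residue_key[1] for p in profile.points]
    pr = [p.pr if (p.pr is not None and p.pr < 1e5) else None for p in profile.points]
    rho = [p.rho for p in profile.points]

    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(10, 5))
    title = f"chain {profile.chain_id} ({profile.mode}"
    title += f" vs {profile.partner})" if profile.partner else ")"
    ax1.set_title(title)
    _plot_segments(ax1, xs, pr, color="tab:red")
    ax1.axhline(params.pr_peak, ls="--", color="k", lw=0.8)
    ax1.axhline(params.pr_base, ls="--", color="k", lw=0.8)
    ax1.set_ylabel("PR")
    _plot_segments(ax2, xs, rho, color="tab:green")
    if profile.rho_mean is not None and profile.rho_sd is not None:
        ax2.axhline(profile.rho_mean - params.rho_sd_factor * profile.rho_sd,
                    ls="--", color="k", lw=0.8)
    ax2.set_ylabel("rho")
    ax2.set_xlabel("residue number")

    index_of = {p.residue_key: i for i, p in enumerate(profile.points)}
    for m in mlips:
        lo = index_of.get(m.span[0])
        hi = index_of.get(m.span[-1])
        if lo is not None and hi is not None:
            for ax in (ax1, ax2):
                ax.axvspan(lo - 0.5, hi + 0.5, color="grey", alpha=0.3)

    step = max(1, len(xs) // 12)
    ax2.set_xticks(xs[::step])
    ax2.set_xticklabels(labels[::step])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_segments(ax, xs, ys, color):
    # plot runs of defined points as separate lines → gaps stay unconnected
    run_x, run_y = [], []
    for x, y in zip(xs, ys):
        if y is None:
            if run_x:
                ax.plot(run_x, run_y, color=color, lw=1.8)
            run_x, run_y = [], []
        else:
            run_x.append(x)
            run_y.append(y)
    if run_x:
        ax.plot(run_x, run_y, color=color, lw=1.8)


def write_bundle(analysis: LipAnalysis, out_dir: str | Path,
                 plots: bool = True) -> list[Path]:
    """Write profile TSVs, the LIP report (JSON), a summary, and plots."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    mlips_by_profile = {}
    for lip in analysis.lips:
        key = (lip.mlip.chain_id, lip.mlip.mode, lip.mlip.partner)
        mlips_by_profile.setdefault(key, []).append(lip.mlip)

    for profile in analysis.profiles:
        key = (profile.chain_id, profile.mode, profile.partner)
        mlips = mlips_by_profile.get(key, [])
        mlip_keys = {k for m in mlips for k in m.span}
        stem = f"profile_{profile.chain_id}_{profile.mode}"
        if profile.partner:
            stem += f"_{profile.partner}"
        tsv_path = out / f"{stem}.tsv"
        tsv_path.write_text(profile_tsv(profile, analysis.structure, mlip_keys))
        written.append(tsv_path)
        if plots:
            png_path = out / f"{stem}.png"
            plot_profile(profile, mlips, analysis.params, png_path)
            written.append(png_path)

    report_path = out / "lips.json"
    report_path.write_text(json.dumps(lip_report_dict(analysis), indent=2) + "\n")
    written.append(report_path)
    summary_path = out / "summary.txt"
    summary_path.write_text(summary_text(analysis))
    written.append(summary_path)
    return written
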