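"""Figure renderers for the plot-kind roster.

Every renderer writes a figure file (svg/png/pdf) and returns a layout
report: a JSON-serializable dict enumerating each drawn data element with
its data-space coordinates.  Tests and provenance logging consume the
report rather than pixels.

Multi-sample plots share one x-axis: data from later samples is carried
onto the first sample's sequence through a position mapping when the
sequences differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import Arc as MplArc
from scipy.stats import gaussian_kde

from ..containers import (
    Annotation,
    InteractionSet,
    Profile,
    Sample,
    SecondaryStructure,
    SequenceRecord,
    TertiaryStructure,
)
from ..errors import AnalysisError, RegistryError
from ..mapping import align_positions, map_data
from .. import profile_analysis as pa
from .. import structure_analysis as sa
from ..registry import PLOT_KINDS
from .geometry import arc_geometry, circle_position, color_class, probability_bin

DEFAULT_ARC_COLORS = {"correct": "grey", "incorrect": "purple",
                      "missing": "green", "primary": "darkblue",
                      "secondary": "lightblue"}


@dataclass
class PlotRequest:
    kind: str
    samples: list[Sample]
    keywords: dict[str, str] = field(default_factory=dict)
    options: dict[str, Any] = field(default_factory=dict)


def _objects(samples: list[Sample], cls) -> list[tuple[Sample, str, Any]]:
    found = []
    for sample in samples:
        for keyword, value in sample.store.items():
            vals = value if isinstance(value, list) else [value]
            for obj in vals:
                if isinstance(obj, cls):
                    found.append((sample, keyword, obj))
    return found


def _require(samples, cls, count, role):
    objs = _objects(samples, cls)
    if len(objs) < count:
        raise AnalysisError(
            f"plot needs {count} object(s) for role {role!r} "
            f"({cls.__name__ if isinstance(cls, type) else cls}); "
            f"found {len(objs)}"
        )
    return objs[:count]


def _pick(samples, keywords, role, cls, count=1):
    """Resolve a role to objects, honouring an explicit keyword choice."""
    if role in keywords:
        objs = []
        for sample in samples:
            if keywords[role] in sample.store:
                value = sample.store[keywords[role]]
                objs += value if isinstance(value, list) else [value]
        if len(objs) < count:
            raise AnalysisError(
                f"keyword {keywords[role]!r} for role {role!r} matched "
                f"{len(objs)} object(s), need {count}"
            )
        return [(samples[0], keywords[role], o) for o in objs[:count]]
    return _require(samples, cls, count, role)


def _shared_axis_profile(anchor: Profile, other: Profile) -> Profile:
    if other.sequence.matches(anchor.sequence):
        return other
    mapping = align_positions(other.sequence, anchor.sequence)
    return map_data(mapping, other)


def _interaction_rows(iset: InteractionSet):
    for (i, j), keep in zip(iset.data[["i", "j"]].to_numpy(int), iset.mask):
        if keep:
            yield int(i), int(j)


# --- individual renderers ---------------------------------------------------

def _render_profile_bars(samples, keywords, options, ax):
    (_, kw, profile), = _pick(samples, keywords, "profile", Profile)
    x = profile.positions
    colors = [profile.colors[color_class(v, profile.breakpoints)]
              if np.isfinite(v) else "lightgrey" for v in profile.values]
    heights = np.where(profile.nodata, 0.0, np.nan_to_num(profile.values))
    ax.bar(x, heights, color=colors, width=1.0)
    ax.set_xlabel("nucleotide position")
    ax.set_ylabel(profile.metric)
    return [{"type": "bar", "keyword": kw, "x": int(p), "height": float(h),
             "color_class": color_class(v, profile.breakpoints)}
            for p, h, v in zip(x, heights, profile.values)]


def _render_skyline(samples, keywords, options, ax):
    profiles = _objects(samples, Profile)
    if not profiles:
        raise AnalysisError("skyline needs at least one profile")
    anchor = profiles[0][2]
    elements = []
    for sample, kw, prof in profiles:
        prof = _shared_axis_profile(anchor, prof)
        y = np.where(prof.nodata, np.nan, prof.values)
        ax.step(prof.positions, y, where="mid", label=f"{sample.label}:{kw}")
        elements.append({"type": "step", "sample": sample.label, "keyword": kw,
                         "x": prof.positions.tolist(),
                         "y": [None if not np.isfinite(v) else float(v) for v in y]})
    ax.legend(fontsize=6)
    ax.set_xlabel("nucleotide position")
    return elements


def _arc_elements(obj, panel: str) -> list[dict]:
    elements = []
    if isinstance(obj, SecondaryStructure):
        rows = [(i, j, "pair", None) for i, j in sorted(obj.pairs)]
    else:
        rows = []
        df = obj.data
        for idx, keep in enumerate(obj.mask):
            if not keep:
                continue
            i, j = int(df.iloc[idx]["i"]), int(df.iloc[idx]["j"])
            label = None
            if "probability" in df.columns:
                label = probability_bin(float(df.iloc[idx]["probability"]))
                if label is None:
                    continue  # below the lowest displayed probability bin
            elif "class_label" in df.columns:
                label = df.iloc[idx]["class_label"]
            rows.append((i, j, "interaction", label))
    for i, j, etype, label in rows:
        cx, r = arc_geometry(i, j)
        elements.append({"type": "arc", "i": i, "j": j, "center": cx,
                         "radius": r, "panel": panel, "etype": etype,
                         "bin": label})
    return elements


def _draw_arcs(ax, elements):
    for el in elements:
        sign = 1 if el["panel"] == "top" else -1
        color = DEFAULT_ARC_COLORS.get(el.get("bin"), "steelblue")
        arc = MplArc((el["center"], 0), 2 * el["radius"], sign * 2 * el["radius"],
                     theta1=0, theta2=180, lw=0.8, color=color)
        ax.add_patch(arc)
    ax.axhline(0, color="black", lw=0.5)
    ax.set_xlabel("nucleotide position")
    ax.set_yticks([])


def _render_arcs(samples, keywords, options, ax):
    (_, kw, obj), = _pick(samples, keywords, "connectivity",
                          (SecondaryStructure, InteractionSet))
    elements = _arc_elements(obj, "top")
    _draw_arcs(ax, elements)
    n = obj.sequence.length
    ax.set_xlim(0, n + 1)
    ax.set_ylim(-1, n / 2 + 1)
    return elements


def _render_arcs_compare(samples, keywords, options, ax):
    objs = _require(samples, (SecondaryStructure, InteractionSet), 2,
                    "connectivity")
    top = _arc_elements(objs[0][2], "top")
    bottom = _arc_elements(objs[1][2], "bottom")
    elements = top + bottom
    _draw_arcs(ax, elements)
    n = objs[0][2].sequence.length
    ax.set_xlim(0, n + 1)
    ax.set_ylim(-(n / 2 + 1), n / 2 + 1)
    return elements


def _render_circle(samples, keywords, options, ax):
    (_, kw, obj), = _pick(samples, keywords, "connectivity",
                          (SecondaryStructure, InteractionSet))
    n = obj.sequence.length
    elements = []
    for k in range(1, n + 1):
        x, y = circle_position(k, n)
        elements.append({"type": "nucleotide", "position": k,
                         "x": float(x), "y": float(y),
                         "angle": 2 * np.pi * k / n})
        ax.plot(x, y, ".", color="black", ms=2)
    pairs = (sorted(obj.pairs) if isinstance(obj, SecondaryStructure)
             else list(_interaction_rows(obj)))
    for i, j in pairs:
        xi, yi = circle_position(i, n)
        xj, yj = circle_position(j, n)
        ax.plot([xi, xj], [yi, yj], color="steelblue", lw=0.6)
        elements.append({"type": "chord", "i": i, "j": j,
                         "xy_i": [float(xi), float(yi)],
                         "xy_j": [float(xj), float(yj)]})
    ax.set_aspect("equal")
    ax.axis("off")
    return elements


def _render_ss_diagram(samples, keywords, options, ax):
    structures = _objects(samples, SecondaryStructure)
    ss = next((s for _, _, s in structures if s.drawing is not None), None)
    if ss is None:
        raise AnalysisError(
            "ss-diagram needs a structure with drawing coordinates; "
            "load a drawing file (varna/xrna/forna/r2dt/nsd)"
        )
    profile = next((p for _, _, p in _objects(samples, Profile)), None)
    isets = [o for _, _, o in _objects(samples, InteractionSet)]
    elements = []
    xy = ss.drawing
    for k, base in enumerate(ss.sequence.residues, 1):
        cc = -1
        if profile is not None and profile.sequence.matches(ss.sequence):
            cc = color_class(profile.values[k - 1], profile.breakpoints)
        color = "lightgrey" if cc < 0 else profile.colors[cc] if profile else "grey"
        ax.text(xy[k - 1, 0], xy[k - 1, 1], base, ha="center", va="center",
                fontsize=5, color=color)
        elements.append({"type": "glyph", "position": k, "base": base,
                         "x": float(xy[k - 1, 0]), "y": float(xy[k - 1, 1]),
                         "color_class": cc})
    for i, j in sorted(ss.pairs):
        ax.plot(xy[[i - 1, j - 1], 0], xy[[i - 1, j - 1], 1],
                color="grey", lw=0.5, zorder=0)
        elements.append({"type": "pair-line", "i": i, "j": j})
    for iset in isets:
        for i, j in _interaction_rows(iset):
            ax.plot(xy[[i - 1, j - 1], 0], xy[[i - 1, j - 1], 1],
                    color="red", lw=0.7, zorder=1)
            elements.append({"type": "interaction-line", "i": i, "j": j,
                             "xy_i": xy[i - 1].tolist(),
                             "xy_j": xy[j - 1].tolist()})
    ax.set_aspect("equal")
    ax.axis("off")
    return elements


def _render_molecule(samples, keywords, options, ax):
    (_, kw, tert), = _pick(samples, keywords, "tertiary", TertiaryStructure)
    isets = [o for _, _, o in _objects(samples, InteractionSet)]
    profile = next((p for _, _, p in _objects(samples, Profile)), None)
    params = options.get("distance_params", sa.DistanceParams())
    elements = []
    export = {"atoms": [], "colors": {}, "cylinders": [], "skipped_cylinders": 0}
    backbone = []
    for resnum in sorted(tert.seq_map):
        pos = tert.seq_map[resnum]
        xyz, used = tert.atom_xyz(pos, params.atom, params.fallback)
        for aname, axyz in tert.residues[resnum].items():
            export["atoms"].append({"residue": resnum, "position": pos,
                                    "atom": aname, "xyz": list(map(float, axyz))})
        if xyz is not None:
            backbone.append((pos, xyz))
        cc = -1
        if profile is not None and pos <= profile.sequence.length:
            cc = color_class(profile.values[pos - 1], profile.breakpoints)
        export["colors"][pos] = cc
    backbone.sort()
    bb = np.array([p[1] for p in backbone])
    if len(bb):
        ax.plot(bb[:, 0], bb[:, 1], color="grey", lw=1.0)  # static xy projection
    for iset in isets:
        for i, j in _interaction_rows(iset):
            a, _ = tert.atom_xyz(i, params.atom, params.fallback)
            b, _ = tert.atom_xyz(j, params.atom, params.fallback)
            if a is None or b is None:
                export["skipped_cylinders"] += 1
                continue
            export["cylinders"].append({"i": i, "j": j,
                                        "start": a.tolist(), "end": b.tolist()})
            ax.plot([a[0], b[0]], [a[1], b[1]], color="red", lw=1.2)
            elements.append({"type": "cylinder", "i": i, "j": j,
                             "start": a.tolist(), "end": b.tolist()})
    ax.set_aspect("equal")
    ax.set_xlabel("x (A)")
    ax.set_ylabel("y (A)")
    elements.append({"type": "export", **export})
    return elements


def _render_heatmap_density(samples, keywords, options, ax):
    (_, kw, iset), = _pick(samples, keywords, "interactions", InteractionSet)
    bin_size = int(options.get("bin_size", 10))
    grid = sa.density_heatmap(iset, bin_size=bin_size)
    ax.imshow(grid.T, origin="lower", cmap="viridis",
              extent=(1, iset.sequence.length, 1, iset.sequence.length))
    ax.set_xlabel("nucleotide i")
    ax.set_ylabel("nucleotide j")
    return [{"type": "heatmap", "bin_size": bin_size,
             "total": float(grid.sum()), "shape": list(grid.shape),
             "grid": grid.tolist()}]


def _render_contour(samples, keywords, options, ax):
    (_, kw, iset), = _pick(samples, keywords, "interactions", InteractionSet)
    pts = np.array(list(_interaction_rows(iset)), dtype=float)
    if len(pts) < 3:
        raise AnalysisError("contour needs >= 3 masked-in interactions")
    try:
        kde = gaussian_kde(pts.T)
        n = iset.sequence.length
        gx, gy = np.meshgrid(np.linspace(1, n, 50), np.linspace(1, n, 50))
        dens = kde(np.vstack([gx.ravel(), gy.ravel()])).reshape(gx.shape)
        ax.contour(gx, gy, dens)
    except np.linalg.LinAlgError:
        raise AnalysisError("interaction positions are degenerate; no contour")
    ax.set_xlabel("nucleotide i")
    ax.set_ylabel("nucleotide j")
    return [{"type": "contour", "n_points": int(len(pts)),
             "points": pts.tolist()}]


def _render_distance_histogram(samples, keywords, options, ax):
    (_, _, iset), = _pick(samples, keywords, "interactions", InteractionSet)
    (_, _, tert), = _pick(samples, keywords, "tertiary", TertiaryStructure)
    counts, bg, edges = sa.distance_histogram(
        iset, tert, bins=options.get("bins"), gap=int(options.get("gap", 10)))
    centers = (edges[:-1] + edges[1:]) / 2
    width = edges[1] - edges[0]
    if bg.sum():
        ax.bar(centers, bg / bg.sum(), width=width, alpha=0.4,
               color="grey", label="all pairs")
    if counts.sum():
        ax.bar(centers, counts / counts.sum(), width=width, alpha=0.6,
               color="red", label="interactions")
    ax.set_xlabel("contact distance (A)")
    ax.set_ylabel("fraction")
    ax.legend(fontsize=6)
    return [{"type": "histogram", "edges": edges.tolist(),
             "counts": counts.tolist(), "background": bg.tolist()}]


def _two_profiles(samples, keywords, require_stderr=False):
    if "profile" not in keywords and require_stderr:
        objs = [t for t in _objects(samples, Profile) if t[2].stderr is not None]
        if len(objs) < 2:
            raise AnalysisError(
                "need two profiles with standard errors; found "
                f"{len(objs)}"
            )
        profs = objs[:2]
    else:
        profs = _pick(samples, keywords, "profile", Profile, count=2)
    a, b = profs[0][2], profs[1][2]
    return a, _shared_axis_profile(a, b), profs


def _render_regression_kde(samples, keywords, options, ax):
    a, b, profs = _two_profiles(samples, keywords)
    result = pa.compare_profiles(a, b)
    x, y = result.table["a"].to_numpy(), result.table["b"].to_numpy()
    try:
        kde = gaussian_kde(np.vstack([x, y]))
        gx, gy = np.meshgrid(np.linspace(x.min(), x.max(), 40),
                             np.linspace(y.min(), y.max(), 40))
        ax.contourf(gx, gy, kde(np.vstack([gx.ravel(), gy.ravel()])).reshape(gx.shape),
                    cmap="Blues")
    except np.linalg.LinAlgError:
        ax.scatter(x, y, s=4)
    xs = np.array([x.min(), x.max()])
    ax.plot(xs, result.slope * xs + result.intercept, color="black", lw=1)
    ax.set_title(f"r = {result.r:.3f} (n = {result.n})", fontsize=8)
    return [{"type": "regression", "slope": result.slope,
             "intercept": result.intercept, "r": result.r, "n": result.n}]


def _render_windowed_auroc(samples, keywords, options, ax):
    (_, _, profile), = _pick(samples, keywords, "profile", Profile)
    (_, _, ss), = _pick(samples, keywords, "structure", SecondaryStructure)
    w = int(options.get("window", 51))
    track = pa.windowed_auroc(profile, ss, pa.WindowParams(w=w))
    x = profile.positions
    ax.plot(x, track.values, color="purple", lw=0.8)
    ax.axhline(0.5, color="grey", ls=":")
    ax.set_ylim(0, 1)
    ax.set_xlabel("nucleotide position")
    ax.set_ylabel(f"AUROC ({w}-nt windows)")
    return [{"type": "auroc-track", "window": w,
             "values": [None if not np.isfinite(v) else float(v)
                        for v in track.values]}]


def _render_deltashape_panel(samples, keywords, options, ax):
    a, b, profs = _two_profiles(samples, keywords, require_stderr=True)
    result = pa.delta_shape(a, b, **{k: options[k] for k in
                                     ("smoothing", "z_multiplier") if k in options})
    x = a.positions
    ax.bar(x, np.nan_to_num(result.difference), color="grey", width=1.0)
    sites = np.flatnonzero(result.sites) + 1
    ax.plot(sites, result.difference[result.sites], "r.", ms=4)
    ax.set_xlabel("nucleotide position")
    ax.set_ylabel("smoothed reactivity difference")
    return [{"type": "deltashape", "sites": sites.tolist(),
             "difference": [None if not np.isfinite(v) else float(v)
                            for v in result.difference]}]


def _render_lowss_panel(samples, keywords, options, fig):
    (_, _, profile), = _pick(samples, keywords, "profile", Profile)
    if "interactions" in keywords:
        (_, _, iset), = _pick(samples, keywords, "interactions", InteractionSet)
    else:  # prefer a pairing-probability set when several are loaded
        isets = [o for _, _, o in _objects(samples, InteractionSet)]
        iset = next((o for o in isets if "probability" in o.data.columns),
                    isets[0] if isets else None)
        if iset is None:
            raise AnalysisError("lowss-panel needs pairing probabilities")
    (_, _, ss), = _pick(samples, keywords, "structure", SecondaryStructure)
    params = options.get("lowss_params", pa.LowSSParams())
    entropy = pa.shannon_entropy(iset)
    regions = pa.find_lowss(profile, entropy, params)
    med_r = pa.windowed_median_profile(profile, params.window)
    med_s = pa.windowed_median_profile(entropy, params.window)
    axes = fig.subplots(3, 1, sharex=True)
    x = profile.positions
    axes[0].plot(x, med_r, color="black", lw=0.8)
    axes[0].axhline(params.r_max, color="grey", ls=":")
    axes[0].set_ylabel("median reactivity")
    axes[1].plot(x, med_s, color="brown", lw=0.8)
    axes[1].axhline(params.s_max, color="grey", ls=":")
    axes[1].set_ylabel("median entropy")
    arc_els = _arc_elements(ss, "top") + _arc_elements(iset, "bottom")
    _draw_arcs(axes[2], arc_els)
    n = profile.sequence.length
    axes[2].set_xlim(0, n + 1)
    axes[2].set_ylim(-(n / 2 + 1), n / 2 + 1)
    for axx in axes:
        for reg in regions:
            axx.axvspan(reg.start, reg.end, color="lightgrey", alpha=0.5)
    elements = [{"type": "lowss-region", "index": r.index,
                 "start": r.start, "end": r.end} for r in regions]
    elements.append({"type": "median-tracks", "window": params.window.w,
                     "n": int(n)})
    return elements + arc_els


def _render_alignment_overview(samples, keywords, options, ax):
    objs = _require(samples, (SequenceRecord, Profile, SecondaryStructure,
                              InteractionSet, TertiaryStructure), 2, "sequence")
    seqs = [getattr(o, "sequence", o) for _, _, o in objs]
    mapping = align_positions(seqs[0], seqs[1])
    mapped = np.zeros(seqs[0].length, dtype=bool)
    for i in mapping.a_to_b:
        mapped[i - 1] = True
    ax.fill_between(np.arange(1, seqs[0].length + 1), 0, mapped.astype(int),
                    step="mid", color="seagreen")
    ax.set_ylim(-0.1, 1.5)
    ax.set_xlabel(f"position in {seqs[0].id}")
    ax.set_yticks([0, 1], ["unmapped", "mapped"])
    return [{"type": "alignment", "seq_a": seqs[0].id, "seq_b": seqs[1].id,
             "n_mapped": mapping.n_mapped, "score": mapping.score,
             "mapped_positions": sorted(mapping.a_to_b)}]


def _render_annotation_track(samples, keywords, options, ax):
    annots = [o for _, _, o in _objects(samples, Annotation)]
    if not annots:
        raise AnalysisError("annotation-track needs annotations")
    elements = []
    for lane, ann in enumerate(annots):
        for start, end in ann.entries:
            lo, hi = min(start, end), max(start, end)
            ax.plot([lo, hi], [lane, lane], lw=6, color=ann.color,
                    solid_capstyle="butt")
            elements.append({"type": "span", "name": ann.name,
                             "category": ann.category, "lane": lane,
                             "start": lo, "end": hi})
    ax.set_yticks(range(len(annots)), [a.name for a in annots], fontsize=6)
    ax.set_xlabel("nucleotide position")
    return elements


def _render_consensus_summary(samples, keywords, options, ax):
    objs = _objects(samples, SecondaryStructure)
    if len(objs) < 2:
        raise AnalysisError("consensus-summary needs >= 2 structure models")
    models = [o for _, _, o in objs]
    table = sa.consensus_pairs(models, min_support=int(
        options.get("min_support", min(3, len(models)))))
    counts = {}
    for support in range(1, table.n_models + 1):
        counts[support] = sum(1 for s in table.support.values() if s == support)
    labels = [f"{s}/{table.n_models} models" for s in counts]
    ax.pie([max(c, 0) for c in counts.values()], labels=labels,
           textprops={"fontsize": 6})
    return [{"type": "pie", "support_counts": counts,
             "union": len(table.union),
             "fraction_shared_by_all": table.fraction_shared_by_all}]


def _render_profile_difference(samples, keywords, options, ax):
    a, b, profs = _two_profiles(samples, keywords)
    diff = np.where(a.nodata | b.nodata, np.nan, a.values - b.values)
    ax.bar(a.positions, np.nan_to_num(diff), color="teal", width=1.0)
    ax.set_xlabel("nucleotide position")
    ax.set_ylabel("reactivity difference")
    return [{"type": "difference",
             "values": [None if not np.isfinite(v) else float(v) for v in diff]}]


_RENDERERS = {
    "profile-bars": _render_profile_bars,
    "skyline": _render_skyline,
    "arcs": _render_arcs,
    "arcs-compare": _render_arcs_compare,
    "circle": _render_circle,
    "ss-diagram": _render_ss_diagram,
    "molecule": _render_molecule,
    "heatmap-density": _render_heatmap_density,
    "contour": _render_contour,
    "distance-histogram": _render_distance_histogram,
    "regression-kde": _render_regression_kde,
    "windowed-auroc": _render_windowed_auroc,
    "deltashape-panel": _render_deltashape_panel,
    "lowss-panel": _render_lowss_panel,
    "alignment-overview": _render_alignment_overview,
    "annotation-track": _render_annotation_track,
    "consensus-summary": _render_consensus_summary,
    "profile-difference": _render_profile_difference,
}

_FIG_LEVEL = {"lowss-panel"}


def render(request: PlotRequest) -> dict:
    """Render a plot request to a file and return its layout report."""
    if request.kind not in _RENDERERS:
        raise RegistryError(
            f"unknown plot kind {request.kind!r}; valid: {sorted(_RENDERERS)}"
        )
    if set(_RENDERERS) != set(PLOT_KINDS):  # registry and renderers in lockstep
        raise RuntimeError("plot registry and renderer table diverged")
    figsize = request.options.get("figsize", (8, 4))
    fig = plt.figure(figsize=figsize)
    try:
        if request.kind in _FIG_LEVEL:
            elements = _RENDERERS[request.kind](
                request.samples, request.keywords, request.options, fig)
        else:
            ax = fig.add_subplot(111)
            elements = _RENDERERS[request.kind](
                request.samples, request.keywords, request.options, ax)
        out = request.options.get("out")
        if out is not None:
            fmt = request.options.get("format")
            fig.savefig(out, format=fmt, dpi=request.options.get("dpi", 150))
        report = {
            "kind": request.kind,
            "samples": [s.label for s in request.samples],
            "out": str(out) if out is not None else None,
            "elements": elements,
        }
        return report
    finally:
        plt.close(fig)
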