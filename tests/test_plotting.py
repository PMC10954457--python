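"""Layout-report assertions for the renderers (data space, not pixels)."""

import numpy as np
import pytest

from probescape import (
    AnalysisError,
    RegistryError,
    arc_geometry,
    circle_position,
    list_plot_kinds,
    plot_options,
)
from probescape.plotting import PlotRequest, render
from probescape.plotting.geometry import color_class, probability_bin


def test_arc_geometry_formula():
    assert arc_geometry(1, 12) == (6.5, 5.5)
    assert arc_geometry(5, 6) == (5.5, 0.5)
    with pytest.raises(AnalysisError):
        arc_geometry(3, 3)


def test_circle_positions_on_unit_circle():
    n = 12
    for k in range(1, n + 1):
        x, y = circle_position(k, n)
        assert np.hypot(x, y) == pytest.approx(1.0)
        theta = 2 * np.pi * k / n
        assert (x, y) == pytest.approx((np.cos(theta), np.sin(theta)))


def test_color_class_breakpoints():
    bp = (0.4, 0.85)
    assert [color_class(v, bp) for v in (0.0, 0.39, 0.4, 0.84, 0.85, 2.0)] == \
        [0, 0, 1, 1, 2, 2]
    assert color_class(float("nan"), bp) == -1


def test_probability_bins():
    assert probability_bin(0.95) == "prob>=0.8"
    assert probability_bin(0.7) == "0.6-0.8"
    assert probability_bin(0.05) is None


def test_all_kinds_render_from_fixture_sample(toy_sample, tmp_path):
    for kind in list_plot_kinds():
        out = tmp_path / f"{kind}.svg"
        report = render(PlotRequest(kind=kind, samples=[toy_sample],
                                    options={"out": str(out)}))
        assert out.exists() and out.stat().st_size > 0, kind
        assert report["kind"] == kind
        assert report["elements"], kind


def test_arc_report_matches_formula(toy_sample, tmp_path, truth):
    report = render(PlotRequest(kind="arcs", samples=[toy_sample],
                                keywords={"connectivity": "ct"},
                                options={"out": str(tmp_path / "a.svg")}))
    arcs = [el for el in report["elements"] if el["type"] == "arc"]
    assert {(a["i"], a["j"]) for a in arcs} == truth.pairs | truth.pk_pairs
    for a in arcs:
        cx, r = arc_geometry(a["i"], a["j"])
        assert (a["center"], a["radius"]) == (cx, r)


def test_circle_report_angles(toy_sample, tmp_path, truth):
    report = render(PlotRequest(kind="circle", samples=[toy_sample],
                                keywords={"connectivity": "ct"},
                                options={"out": str(tmp_path / "c.svg")}))
    n = truth.spec.n
    nts = [el for el in report["elements"] if el["type"] == "nucleotide"]
    assert len(nts) == n
    for el in nts:
        assert el["angle"] == pytest.approx(2 * np.pi * el["position"] / n)


def test_skyline_shares_x_axis(toy_sample, tmp_path):
    report = render(PlotRequest(kind="skyline", samples=[toy_sample],
                                options={"out": str(tmp_path / "s.svg")}))
    steps = [el for el in report["elements"] if el["type"] == "step"]
    assert len(steps) >= 2
    assert all(s["x"] == steps[0]["x"] for s in steps)


def test_ss_diagram_glyphs_at_drawing_coordinates(toy_sample, tmp_path, truth):
    report = render(PlotRequest(kind="ss-diagram", samples=[toy_sample],
                                options={"out": str(tmp_path / "d.svg")}))
    glyphs = [el for el in report["elements"] if el["type"] == "glyph"]
    assert len(glyphs) == truth.spec.n
    for g in glyphs[:10]:
        x, y = truth.drawing[g["position"] - 1]
        assert (g["x"], g["y"]) == pytest.approx((x, y), abs=1e-3)
        # colour classes come from the profile breakpoints
        assert g["color_class"] in (-1, 0, 1, 2)


def test_molecule_cylinders_use_contact_atoms(toy_sample, tmp_path):
    from probescape import structure_analysis as sa
    report = render(PlotRequest(kind="molecule", samples=[toy_sample],
                                options={"out": str(tmp_path / "m.svg")}))
    tert = toy_sample.get("pdb")
    cylinders = [el for el in report["elements"] if el["type"] == "cylinder"]
    assert cylinders
    for cyl in cylinders:
        length = float(np.linalg.norm(np.array(cyl["start"]) -
                                      np.array(cyl["end"])))
        assert length == pytest.approx(
            sa.contact_distance(tert, cyl["i"], cyl["j"]), abs=1e-6)


def test_heatmap_total_equals_mask_count(toy_sample, tmp_path):
    ring = toy_sample.get("ring")
    report = render(PlotRequest(kind="heatmap-density", samples=[toy_sample],
                                keywords={"interactions": "ring"},
                                options={"out": str(tmp_path / "h.svg")}))
    (hm,) = report["elements"]
    assert hm["total"] == ring.mask.sum()


def test_missing_requirement_is_an_error(tmp_path):
    from probescape.containers import Sample
    with pytest.raises(AnalysisError, match="profile"):
        render(PlotRequest(kind="profile-bars", samples=[Sample("empty")],
                           options={"out": str(tmp_path / "x.svg")}))


def test_unknown_kind_is_registry_error(toy_sample):
    with pytest.raises(RegistryError):
        render(PlotRequest(kind="nonsense", samples=[toy_sample]))


def test_renderable_kinds_cover_plot_options(toy_sample, tmp_path):
    assert set(plot_options(toy_sample)) == set(list_plot_kinds())
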