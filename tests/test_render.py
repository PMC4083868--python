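"""Color rules, pixel probes, bar heights, layout arithmetic, export."""

import colorsys

import numpy as np
import pytest
from PIL import Image

from hapcanvas import (
    Allele,
    RenderOptions,
    SubjectGroup,
    aggregate_rows,
    cell_color_genotype,
    cell_color_nucleotide,
    cell_color_reference,
    export_image,
    meta_color,
    render_matrix,
)
from hapcanvas.hapstore import MetaTable
from hapcanvas.render import (
    DEFAULT_GT_HET,
    DEFAULT_GT_HOM,
    DEFAULT_GT_REF,
    DEFAULT_NUCLEOTIDE_PALETTE,
    DEFAULT_REF_MATCH,
    DEFAULT_REF_MISMATCH,
    WHITE,
    category_color_map,
)

from conftest import make_matrix, A, C, G, T, MISS

PLAIN = RenderOptions(show_subject_ids=False, show_variant_ids=False)


def saturation(color):
    return colorsys.rgb_to_hsv(*(c / 255 for c in color))[1]


class TestCellColors:
    def test_nucleotide_defaults(self):
        # A green, C blue, T red, G yellow; missing white
        assert cell_color_nucleotide(Allele.A) == (77, 175, 74)
        assert cell_color_nucleotide(Allele.C) == (55, 126, 184)
        assert cell_color_nucleotide(Allele.T) == (228, 26, 28)
        assert cell_color_nucleotide(Allele.G) == (255, 255, 51)
        assert cell_color_nucleotide(Allele.MISSING) == WHITE

    def test_nucleotide_palette_override(self):
        pal = dict(DEFAULT_NUCLEOTIDE_PALETTE)
        pal[Allele.A] = (1, 2, 3)
        assert cell_color_nucleotide(Allele.A, pal) == (1, 2, 3)

    def test_reference_encoding(self):
        assert cell_color_reference(Allele.G, Allele.C) == DEFAULT_REF_MISMATCH
        assert cell_color_reference(Allele.C, Allele.C) == DEFAULT_REF_MATCH
        assert cell_color_reference(Allele.MISSING, Allele.C) == WHITE
        with pytest.raises(ValueError):
            cell_color_reference(Allele.A, Allele.MISSING)

    def test_genotype_encoding(self):
        ref = Allele.C
        assert cell_color_genotype(Allele.G, Allele.G, ref) == DEFAULT_GT_HOM
        assert cell_color_genotype(Allele.C, Allele.G, ref) == DEFAULT_GT_HET
        assert cell_color_genotype(Allele.C, Allele.C, ref) == DEFAULT_GT_REF
        assert cell_color_genotype(Allele.MISSING, Allele.C, ref) == WHITE

    def test_every_combination_maps_to_one_color(self):
        states = list(Allele)
        bases = [a for a in states if a is not Allele.MISSING]
        for a in states:
            assert isinstance(cell_color_nucleotide(a), tuple)
            for ref in bases:
                assert isinstance(cell_color_reference(a, ref), tuple)
                for b in states:
                    assert isinstance(cell_color_genotype(a, b, ref), tuple)


class TestMetaColor:
    def test_numerical_gradient_endpoints(self):
        import matplotlib as mpl

        lo = meta_color(0.0, "numerical", "viridis", 0.0, 10.0)
        expected = tuple(round(c * 255) for c in mpl.colormaps["viridis"](0.0)[:3])
        assert lo == expected

    def test_equal_labels_equal_colors_first_seen_order(self):
        cmap = category_color_map(["EUR", "AFR", "EUR", "ASN"])
        assert list(cmap) == ["EUR", "AFR", "ASN"]
        assert meta_color("AFR", "categorical", category_map=cmap) == cmap["AFR"]

    def test_absent_value_is_white(self):
        assert meta_color(None, "numerical") == WHITE
        assert meta_color(None, "categorical") == WHITE

    def test_five_label_assignment_matches_order_oracle(self):
        labels = ["d", "b", "a", "c", "e", "b", "a"]
        cmap = category_color_map(labels)
        seen = list(dict.fromkeys(labels))
        from hapcanvas.render import DEFAULT_CATEGORY_COLORS

        assert cmap == {
            lab: DEFAULT_CATEGORY_COLORS[i] for i, lab in enumerate(seen)
        }


@pytest.fixture
def probe_matrix():
    """3 subjects x 5 SNVs with designed cells for every color rule."""
    calls = np.array(
        [
            [[C, G], [A, A], [T, T], [C, C], [G, C]],
            [[C, C], [A, T], [T, G], [MISS, C], [G, G]],
            [[G, G], [T, T], [MISS, MISS], [C, G], [C, C]],
        ],
        dtype=np.uint8,
    )
    return make_matrix(calls, refs=[C, A, T, C, C], alts=[G, T, G, G, G])


class TestRenderPixels:
    def test_layout_arithmetic(self, probe_matrix):
        opts = RenderOptions(cell_w=7, cell_h=5, show_subject_ids=False,
                             show_variant_ids=False)
        canvas = render_matrix(probe_matrix, opts=opts)
        # phased: 2 display columns per SNV, P/M meta row below (+2 px gap)
        assert canvas.width == 5 * 2 * 7
        assert canvas.height == 3 * 5 + 2 + 12

    def test_pixel_probe_all_encodings(self, probe_matrix):
        for encoding in ("nucleotide", "reference", "genotype"):
            opts = RenderOptions(encoding=encoding, cell_w=6, cell_h=6,
                                 show_subject_ids=False, show_variant_ids=False)
            canvas = render_matrix(probe_matrix, opts=opts)
            calls = probe_matrix.calls()
            for r in range(3):
                for j, v in enumerate(probe_matrix.variants):
                    if encoding == "genotype":
                        expect = cell_color_genotype(
                            Allele(int(calls[r, j, 0])), Allele(int(calls[r, j, 1])),
                            v.ref) if MISS not in calls[r, j] else WHITE
                        got = canvas.pixel(*canvas.cell_center(r, canvas.display_col(j)))
                        assert got == expect, (encoding, r, j)
                    else:
                        for k in range(2):
                            a = Allele(int(calls[r, j, k]))
                            if encoding == "nucleotide":
                                expect = cell_color_nucleotide(a)
                            else:
                                expect = (WHITE if a is Allele.MISSING
                                          else cell_color_reference(a, v.ref))
                            got = canvas.pixel(
                                *canvas.cell_center(r, canvas.display_col(j, k)))
                            assert got == expect, (encoding, r, j, k)

    def test_pm_row_colors(self, probe_matrix):
        opts = RenderOptions(cell_w=6, cell_h=6, show_subject_ids=False,
                             show_variant_ids=False)
        canvas = render_matrix(probe_matrix, opts=opts)
        y = 3 * 6 + 2 + 6  # grid + gap + middle of the P/M row
        from hapcanvas.render import PM_COLORS

        assert canvas.pixel(3, y) == PM_COLORS["P"]
        assert canvas.pixel(9, y) == PM_COLORS["M"]

    def test_zero_size_matrix_rejected(self, probe_matrix):
        empty = probe_matrix.slice(variant_indices=[])
        with pytest.raises(ValueError, match="zero-size"):
            render_matrix(empty, opts=PLAIN)

    def test_selection_outline_drawn(self, probe_matrix):
        opts = RenderOptions(cell_w=6, cell_h=6, selected_rows=(1,),
                             show_subject_ids=False, show_variant_ids=False)
        canvas = render_matrix(probe_matrix, opts=opts)
        x, y, _, _ = canvas.cell_rect(1, 0)
        assert canvas.pixel(x, y) == (0, 0, 0)

    def test_meta_panels_rendered(self, probe_matrix):
        smeta = MetaTable("subject", probe_matrix.subject_ids,
                          [("Pop", "categorical",
                            {"S1": "X", "S2": "X", "S3": "Y"})])
        vmeta = MetaTable("variant", probe_matrix.variant_ids,
                          [("Gene", "categorical",
                            {v: "g1" for v in probe_matrix.variant_ids})])
        opts = RenderOptions(cell_w=6, cell_h=6, meta_cell_w=6, meta_cell_h=6,
                             show_subject_ids=False, show_variant_ids=False)
        canvas = render_matrix(probe_matrix, smeta, vmeta, opts)
        assert canvas.width == 5 * 2 * 6 + 2 + 6       # grid + gap + 1 meta col
        assert canvas.height == 3 * 6 + 2 + 2 * 6      # grid + gap + P/M + Gene
        cmap = category_color_map(["X", "X", "Y"])
        assert canvas.pixel(5 * 2 * 6 + 2 + 3, 3) == cmap["X"]
        assert canvas.pixel(5 * 2 * 6 + 2 + 3, 15) == cmap["Y"]

    def test_determinism_byte_identical(self, probe_matrix):
        opts = RenderOptions(cell_w=5, cell_h=5)
        a = render_matrix(probe_matrix, opts=opts)
        b = render_matrix(probe_matrix, opts=opts)
        assert np.array_equal(a.rgb, b.rgb)


class TestAggregatedRendering:
    def _agg(self, probe_matrix, method="maximum"):
        groups = [SubjectGroup("g1", ("S1", "S2")), SubjectGroup("g2", ("S3",))]
        return aggregate_rows(probe_matrix, groups, method)

    def test_bar_full_height_at_unit_frequency(self, probe_matrix):
        agg = self._agg(probe_matrix)
        opts = RenderOptions(aggregate_mode="bar", cell_w=6, cell_h=10,
                             show_subject_ids=False, show_variant_ids=False)
        canvas = render_matrix(agg, opts=opts)
        # singleton group g2 at rs4 column P: call C (ref) -> f = 1.0
        col = canvas.display_col(3, 0)
        x, y, w, h = canvas.cell_rect(1, col)
        color = cell_color_nucleotide(Allele.C)
        assert canvas.pixel(x + w // 2, y) == color          # top of cell filled
        assert canvas.pixel(x + w // 2, y + h - 1) == color

    def test_bar_height_is_round_f_cell_h(self, probe_matrix):
        agg = self._agg(probe_matrix)
        gi, j, k = 0, 0, 0  # members S1,S2 at rs1 P: C,C -> actually f=1; use M col
        # rs1 M column: S1=G, S2=C -> maximum consensus C (tie-break), f=0.5
        opts = RenderOptions(aggregate_mode="bar", cell_w=6, cell_h=10,
                             show_subject_ids=False, show_variant_ids=False)
        canvas = render_matrix(agg, opts=opts)
        col = canvas.display_col(0, 1)
        x, y, w, h = canvas.cell_rect(0, col)
        cell = agg.cell(0, 0, 1)
        expected_bar = round(cell.frequency * 10)
        column = canvas.rgb[y:y + h, x + w // 2]
        n_colored = int((column != 255).any(axis=1).sum())
        assert n_colored == expected_bar

    def test_rarity_bars_invert_height(self, probe_matrix):
        agg = self._agg(probe_matrix, "minimum")
        opts = RenderOptions(aggregate_mode="bar", rarity_bars=True,
                             cell_w=6, cell_h=10,
                             show_subject_ids=False, show_variant_ids=False)
        canvas = render_matrix(agg, opts=opts)
        col = canvas.display_col(0, 1)
        x, y, w, h = canvas.cell_rect(0, col)
        cell = agg.cell(0, 0, 1)
        expected_bar = round((1 - cell.frequency) * 10)
        column = canvas.rgb[y:y + h, x + w // 2]
        assert int((column != 255).any(axis=1).sum()) == expected_bar

    def test_saturation_monotone_in_frequency(self):
        # one group, three sites with consensus-T frequencies 1/3, 2/3, 1.0
        calls = np.array(
            [[[T, T], [T, T], [T, T]],
             [[A, A], [T, T], [T, T]],
             [[G, G], [A, A], [T, T]]], dtype=np.uint8)
        m = make_matrix(calls, refs=[C, C, C], alts=[T, T, T])
        agg = aggregate_rows(m, [SubjectGroup("all", tuple(m.subject_ids))],
                             "maximum")
        opts = RenderOptions(aggregate_mode="saturation", cell_w=4, cell_h=4,
                             show_subject_ids=False, show_variant_ids=False)
        canvas = render_matrix(agg, opts=opts)
        sats = [
            saturation(canvas.pixel(*canvas.cell_center(0, canvas.display_col(j, 0))))
            for j in range(3)
        ]
        assert sats[0] < sats[1] < sats[2]

    def test_agn_row_labels(self, probe_matrix):
        agg = self._agg(probe_matrix)
        canvas = render_matrix(agg, opts=PLAIN)
        assert canvas.row_labels == ["AGN2", "AGN1"]

    def test_all_missing_aggregate_cell_white(self):
        calls = np.full((2, 1, 2), MISS, dtype=np.uint8)
        m = make_matrix(calls)
        agg = aggregate_rows(m, [SubjectGroup("all", ("S1", "S2"))], "maximum")
        for mode in ("saturation", "bar"):
            opts = RenderOptions(aggregate_mode=mode, cell_w=4, cell_h=4,
                                 show_subject_ids=False, show_variant_ids=False)
            canvas = render_matrix(agg, opts=opts)
            assert canvas.pixel(*canvas.cell_center(0, 0)) == WHITE


class TestExport:
    @pytest.mark.parametrize("fmt", ["png", "jpeg", "tiff", "svg", "pdf"])
    def test_all_formats_nonempty(self, probe_matrix, tmp_path, fmt):
        canvas = render_matrix(probe_matrix, opts=PLAIN)
        out = tmp_path / f"fig.{fmt}"
        export_image(canvas, out)
        assert out.exists() and out.stat().st_size > 0

    def test_png_reopens_with_expected_dimensions(self, probe_matrix, tmp_path):
        canvas = render_matrix(probe_matrix, opts=PLAIN)
        out = tmp_path / "fig.png"
        export_image(canvas, out)
        with Image.open(out) as img:
            assert img.size == (canvas.width, canvas.height)
            assert np.array_equal(np.asarray(img.convert("RGB")), canvas.rgb)

    def test_unsupported_format_lists_the_five(self, probe_matrix, tmp_path):
        canvas = render_matrix(probe_matrix, opts=PLAIN)
        with pytest.raises(ValueError, match="png.*jpeg.*tiff.*svg.*pdf"):
            export_image(canvas, tmp_path / "fig.bmp")

    def test_subregion_width_scales_with_variant_count(self, probe_matrix, tmp_path):
        canvas = render_matrix(probe_matrix, opts=PLAIN)
        full = tmp_path / "full.png"
        part = tmp_path / "part.png"
        export_image(canvas, full, region=((0, 3), (0, 5)))
        export_image(canvas, part, region=((0, 3), (0, 2)))
        with Image.open(full) as fi, Image.open(part) as pi:
            assert fi.size[0] == 5 * 2 * canvas.cell_w
            assert pi.size[0] == 2 * 2 * canvas.cell_w

    def test_png_export_deterministic_bytes(self, probe_matrix, tmp_path):
        canvas = render_matrix(probe_matrix, opts=RenderOptions())
        a, b = tmp_path / "a.png", tmp_path / "b.png"
        export_image(canvas, a)
        export_image(canvas, b)
        assert a.read_bytes() == b.read_bytes()


class TestOptions:
    def test_validation(self):
        with pytest.raises(ValueError):
            RenderOptions(encoding="rainbow")
        with pytest.raises(ValueError):
            RenderOptions(cell_w=0)
        with pytest.raises(ValueError):
            RenderOptions(aggregate_mode="stacked")

    def test_yaml_round_trip(self, tmp_path):
        cfg = tmp_path / "opts.yaml"
        cfg.write_text(
            "encoding: reference\n"
            "cell_w: 9\n"
            "cell_h: 7\n"
            "aggregate_mode: bar\n"
            "nucleotide_palette:\n"
            "  A: [0, 255, 0]\n"
            "  C: [0, 0, 255]\n"
            "  G: [255, 255, 0]\n"
            "  T: [255, 0, 0]\n"
            "  '-': [255, 255, 255]\n"
            "selection_color: [10, 10, 10]\n"
        )
        opts = RenderOptions.from_yaml(cfg)
        assert opts.encoding == "reference"
        assert (opts.cell_w, opts.cell_h) == (9, 7)
        assert opts.nucleotide_palette[Allele.A] == (0, 255, 0)
        assert opts.selection_color == (10, 10, 10)

    def test_genotype_encoding_needs_two_columns(self):
        calls = np.zeros((2, 2, 1), dtype=np.uint8)
        m = make_matrix(calls, phased=False)
        with pytest.raises(ValueError, match="two allele columns"):
            render_matrix(m, opts=RenderOptions(encoding="genotype"))
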