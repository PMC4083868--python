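"""Static rendering of haplotype and aggregated matrices.

The view is a heatmap-like grid: one row per subject (or per aggregated
group) and, for phased data, two adjacent columns per SNV — allele-column 0
("P") and 1 ("M").  Three color encodings are available:

* ``nucleotide`` — each base gets its own color (defaults: A green, C blue,
  T red, G yellow; missing calls white);
* ``reference`` — blue where the allele equals the reference base, yellow
  where it differs, white for missing;
* ``genotype`` — one column per SNV: green when both alleles equal the
  reference, red for homozygous non-reference, yellow for heterozygous,
  white if either allele is missing.  This is the natural encoding for
  unphased data.

Aggregated cells are drawn either as boxes whose color saturation grows
with the consensus-base frequency, or as bottom-anchored bars whose height
is ``round(f * cell_h)`` pixels.  Subject meta-information columns are
drawn right of the grid, variant meta rows (including the automatic "P/M"
row for phased data) below it.  Default colors are qualitative
ColorBrewer-style picks; all are overridable, and the exact RGB values are
this package's documented defaults rather than a claim of pixel parity
with any other tool.

Export formats: PNG, JPEG, TIFF (raster, via Pillow), SVG and PDF (vector
containers, via matplotlib).
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from PIL import Image, ImageDraw, ImageFont

from .aggregate import AggregatedMatrix, aggregate_meta_column
from .hapstore import Allele, MISSING_CODE, HaplotypeMatrix, MetaTable

__all__ = [
    "Color",
    "RenderOptions",
    "Canvas",
    "cell_color_nucleotide",
    "cell_color_reference",
    "cell_color_genotype",
    "meta_color",
    "render_matrix",
    "export_image",
    "EXPORT_FORMATS",
]

Color = tuple[int, int, int]

WHITE: Color = (255, 255, 255)
BLACK: Color = (0, 0, 0)

# qualitative ColorBrewer-style defaults (Set1)
DEFAULT_NUCLEOTIDE_PALETTE: dict[Allele, Color] = {
    Allele.A: (77, 175, 74),     # green
    Allele.C: (55, 126, 184),    # blue
    Allele.T: (228, 26, 28),     # red
    Allele.G: (255, 255, 51),    # yellow
    Allele.MISSING: WHITE,
}
DEFAULT_REF_MATCH: Color = (55, 126, 184)      # blue
DEFAULT_REF_MISMATCH: Color = (255, 255, 51)   # yellow
DEFAULT_GT_REF: Color = (77, 175, 74)          # green
DEFAULT_GT_HET: Color = (255, 255, 51)         # yellow
DEFAULT_GT_HOM: Color = (228, 26, 28)          # red

DEFAULT_CATEGORY_COLORS: tuple[Color, ...] = (  # Set3-like qualitative cycle
    (141, 211, 199), (255, 255, 179), (190, 186, 218), (251, 128, 114),
    (128, 177, 211), (253, 180, 98), (179, 222, 105), (252, 205, 229),
    (217, 217, 217), (188, 128, 189), (204, 235, 197), (255, 237, 111),
    (166, 206, 227), (31, 120, 180), (178, 223, 138), (51, 160, 44),
)

PM_COLORS: dict[str, Color] = {"P": (226, 226, 226), "M": (196, 196, 196)}

ENCODINGS = ("nucleotide", "reference", "genotype")
AGGREGATE_MODES = ("saturation", "bar")
EXPORT_FORMATS = ("png", "jpeg", "tiff", "svg", "pdf")

_LABEL_W = 72   # left margin for row identifiers, px
_LABEL_H = 30   # top margin for column identifiers, px
_GAP = 2        # px between grid and meta panels


@dataclass(frozen=True)
class RenderOptions:
    """Everything tunable about the static view.

    ``cell_w``/``cell_h`` play the role of the zoom level; 1x1-pixel cells
    are valid.  ``rarity_bars`` inverts bar heights (height ~ 1 - f) so
    that a minimum-method aggregation visually emphasises rarity.
    """

    encoding: str = "nucleotide"
    cell_w: int = 12
    cell_h: int = 12
    aggregate_mode: str = "saturation"
    rarity_bars: bool = False
    nucleotide_palette: Mapping[Allele, Color] = field(
        default_factory=lambda: dict(DEFAULT_NUCLEOTIDE_PALETTE))
    ref_match_color: Color = DEFAULT_REF_MATCH
    ref_mismatch_color: Color = DEFAULT_REF_MISMATCH
    genotype_ref_color: Color = DEFAULT_GT_REF
    genotype_het_color: Color = DEFAULT_GT_HET
    genotype_hom_color: Color = DEFAULT_GT_HOM
    missing_color: Color = WHITE
    saturation_floor: float = 0.15
    meta_cell_w: int = 12
    meta_cell_h: int = 12
    numerical_gradient: str = "viridis"
    category_colors: tuple[Color, ...] = DEFAULT_CATEGORY_COLORS
    selection_color: Color = BLACK
    selected_rows: tuple[int, ...] = ()
    selected_cols: tuple[int, ...] = ()
    show_subject_ids: bool = True
    show_variant_ids: bool = True

    def __post_init__(self) -> None:
        if self.encoding not in ENCODINGS:
            raise ValueError(f"encoding must be one of {ENCODINGS}")
        if self.aggregate_mode not in AGGREGATE_MODES:
            raise ValueError(f"aggregate_mode must be one of {AGGREGATE_MODES}")
        if self.cell_w < 1 or self.cell_h < 1:
            raise ValueError("cell_w and cell_h must be >= 1 pixel")
        if not 0.0 <= self.saturation_floor < 1.0:
            raise ValueError("saturation_floor must be in [0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RenderOptions":
        """Load options from a YAML mapping; unknown keys are rejected."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"render config must be a mapping: {path}")
        kwargs: dict = {}
        for key, value in raw.items():
            if key == "nucleotide_palette":
                kwargs[key] = {
                    Allele.from_symbol(sym): tuple(rgb) for sym, rgb in value.items()
                }
            elif key.endswith("_color") or key == "category_colors":
                kwargs[key] = (
                    tuple(tuple(c) for c in value)
                    if key == "category_colors" else tuple(value)
                )
            elif key in ("selected_rows", "selected_cols"):
                kwargs[key] = tuple(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# per-cell color rules

def cell_color_nucleotide(
    a: Allele, palette: Mapping[Allele, Color] | None = None
) -> Color:
    """Unique color per base; MISSING is white (or the palette override)."""
    palette = DEFAULT_NUCLEOTIDE_PALETTE if palette is None else palette
    return tuple(palette[Allele(a)])


def cell_color_reference(
    a: Allele,
    ref: Allele,
    match: Color = DEFAULT_REF_MATCH,
    mismatch: Color = DEFAULT_REF_MISMATCH,
    missing: Color = WHITE,
) -> Color:
    """Blue if the allele equals the reference base, yellow otherwise."""
    a, ref = Allele(a), Allele(ref)
    if ref is Allele.MISSING:
        raise ValueError("reference base must be concrete")
    if a is Allele.MISSING:
        return missing
    return match if a == ref else mismatch


def cell_color_genotype(
    a0: Allele,
    a1: Allele,
    ref: Allele,
    ref_color: Color = DEFAULT_GT_REF,
    het_color: Color = DEFAULT_GT_HET,
    hom_color: Color = DEFAULT_GT_HOM,
    missing: Color = WHITE,
) -> Color:
    """Green = both alleles reference, red = homozygous alt, yellow = het."""
    a0, a1, ref = Allele(a0), Allele(a1), Allele(ref)
    if ref is Allele.MISSING:
        raise ValueError("reference base must be concrete")
    if Allele.MISSING in (a0, a1):
        return missing
    if a0 == ref and a1 == ref:
        return ref_color
    if a0 == a1:
        return hom_color
    return het_color


def meta_color(
    value,
    kind: str,
    gradient: str = "viridis",
    vmin: float = 0.0,
    vmax: float = 1.0,
    category_map: Mapping[str, Color] | None = None,
) -> Color:
    """Color for one meta value: gradient for numbers, stable map for labels."""
    if value is None:
        return WHITE
    if kind == "numerical":
        import matplotlib as mpl

        span = vmax - vmin
        t = 0.5 if span == 0 else (float(value) - vmin) / span
        r, g, b, _ = mpl.colormaps[gradient](float(np.clip(t, 0.0, 1.0)))
        return (round(r * 255), round(g * 255), round(b * 255))
    if category_map is None or str(value) not in category_map:
        return WHITE
    return tuple(category_map[str(value)])


def category_color_map(
    labels_in_order: Sequence[str],
    colors: Sequence[Color] = DEFAULT_CATEGORY_COLORS,
) -> dict[str, Color]:
    """Stable label -> color assignment in first-seen order, cycling."""
    mapping: dict[str, Color] = {}
    for lab in labels_in_order:
        if lab is None or lab in mapping:
            continue
        mapping[lab] = tuple(colors[len(mapping) % len(colors)])
    return mapping


def _saturate(color: Color, f: float, floor: float) -> Color:
    """Scale a color's HSV saturation by ``floor + (1 - floor) * f``."""
    h, s, v = colorsys.rgb_to_hsv(*(c / 255.0 for c in color))
    s2 = s * (floor + (1.0 - floor) * float(f))
    r, g, b = colorsys.hsv_to_rgb(h, s2, v)
    return (round(r * 255), round(g * 255), round(b * 255))


# ---------------------------------------------------------------------------
# layout + canvas

@dataclass
class Canvas:
    """Rendered RGB raster plus the layout needed to address it.

    ``rgb`` is an (H, W, 3) uint8 array.  Grid geometry is exposed so tests
    and sub-region export can address individual cells.
    """

    rgb: np.ndarray
    grid_x: int
    grid_y: int
    cell_w: int
    cell_h: int
    n_rows: int
    n_display_cols: int
    cols_per_variant: int
    row_labels: list[str]

    @property
    def width(self) -> int:
        return self.rgb.shape[1]

    @property
    def height(self) -> int:
        return self.rgb.shape[0]

    def display_col(self, j: int, k: int = 0) -> int:
        """Display-grid column of variant *j*, allele-column *k*."""
        return j * self.cols_per_variant + (k if self.cols_per_variant > 1 else 0)

    def cell_rect(self, row: int, col: int) -> tuple[int, int, int, int]:
        """(x0, y0, w, h) pixel rectangle of one grid cell."""
        return (
            self.grid_x + col * self.cell_w,
            self.grid_y + row * self.cell_h,
            self.cell_w,
            self.cell_h,
        )

    def cell_center(self, row: int, col: int) -> tuple[int, int]:
        x, y, w, h = self.cell_rect(row, col)
        return (x + w // 2, y + h // 2)

    def pixel(self, x: int, y: int) -> Color:
        return tuple(int(c) for c in self.rgb[y, x])

    def to_image(self) -> Image.Image:
        return Image.fromarray(self.rgb, mode="RGB")


def _fill(rgb: np.ndarray, x: int, y: int, w: int, h: int, color: Color) -> None:
    rgb[y:y + h, x:x + w] = color


def _outline(rgb: np.ndarray, x: int, y: int, w: int, h: int, color: Color) -> None:
    rgb[y, x:x + w] = color
    rgb[y + h - 1, x:x + w] = color
    rgb[y:y + h, x] = color
    rgb[y:y + h, x + w - 1] = color


def render_matrix(
    data: HaplotypeMatrix | AggregatedMatrix,
    subject_meta: MetaTable | None = None,
    variant_meta: MetaTable | None = None,
    opts: RenderOptions | None = None,
) -> Canvas:
    """Render a haplotype or aggregated matrix to an RGB canvas.

    Canvas dimensions are exact affine functions of the matrix shape and
    the cell sizes.  For an :class:`AggregatedMatrix`, cells are drawn in
    the configured ``aggregate_mode`` and rows are labelled "AGN<k>"; a
    subject meta table, if given, is summarised per group (mode for
    categorical columns, mean for numerical ones).
    """
    opts = opts or RenderOptions()
    aggregated = isinstance(data, AggregatedMatrix)
    m = data.n_variants
    p = data.n_allele_columns
    if aggregated:
        n_rows = data.n_groups
        row_ids = data.labels
    else:
        n_rows = data.n_subjects
        row_ids = list(data.subject_ids)
    if n_rows == 0 or m == 0:
        raise ValueError("cannot render a zero-size matrix")
    if opts.encoding == "genotype" and p != 2:
        raise ValueError("the genotype encoding needs two allele columns per SNV")

    cols_per_variant = 1 if opts.encoding == "genotype" else p
    n_cols = m * cols_per_variant

    label_w = _LABEL_W if opts.show_subject_ids else 0
    label_h = _LABEL_H if opts.show_variant_ids else 0
    grid_w, grid_h = n_cols * opts.cell_w, n_rows * opts.cell_h

    sm_cols = subject_meta.column_names if subject_meta is not None else []
    vm_rows = variant_meta.column_names if variant_meta is not None else []
    pm_row = bool(data.phased and p == 2 and cols_per_variant == 2)

    meta_w = (len(sm_cols) * opts.meta_cell_w + _GAP) if sm_cols else 0
    n_bottom = len(vm_rows) + (1 if pm_row else 0)
    meta_h = (n_bottom * opts.meta_cell_h + _GAP) if n_bottom else 0

    W = label_w + grid_w + meta_w
    H = label_h + grid_h + meta_h
    rgb = np.full((H, W, 3), 255, dtype=np.uint8)
    canvas = Canvas(rgb, label_w, label_h, opts.cell_w, opts.cell_h,
                    n_rows, n_cols, cols_per_variant, row_ids)

    # --- haplotype grid ----------------------------------------------------
    if aggregated:
        _draw_aggregated_cells(rgb, canvas, data, opts)
    else:
        _draw_subject_cells(rgb, canvas, data, opts)

    # --- selection outlines ------------------------------------------------
    for r in opts.selected_rows:
        x, y, _, h = canvas.cell_rect(r, 0)
        _outline(rgb, x, y, grid_w, h, opts.selection_color)
    for c in opts.selected_cols:
        x, y, w, _ = canvas.cell_rect(0, c)
        _outline(rgb, x, y, w, grid_h, opts.selection_color)

    # --- subject meta panel (right) ----------------------------------------
    if sm_cols:
        x0 = label_w + grid_w + _GAP
        for ci, cname in enumerate(sm_cols):
            kind = subject_meta.kind(cname)
            column = subject_meta.column(cname)
            if kind == "numerical":
                vals = list(column.values())
                vmin, vmax = (min(vals), max(vals)) if vals else (0.0, 1.0)
                cmap = None
            else:
                cmap = category_color_map(
                    [column.get(i) for i in subject_meta.ids if column.get(i)],
                    opts.category_colors,
                )
                vmin = vmax = 0.0
            for r in range(n_rows):
                if aggregated:
                    members = data.groups[r].member_ids
                    method = "mean" if kind == "numerical" else "mode"
                    value = aggregate_meta_column(
                        [column.get(s) for s in members], kind, method
                    )
                else:
                    value = column.get(row_ids[r])
                color = meta_color(value, kind, opts.numerical_gradient,
                                   vmin, vmax, cmap)
                _fill(rgb, x0 + ci * opts.meta_cell_w, label_h + r * opts.cell_h,
                      opts.meta_cell_w, opts.cell_h, color)

    # --- variant meta rows + P/M row (bottom) ------------------------------
    y0 = label_h + grid_h + (_GAP if n_bottom else 0)
    bottom_rows: list[tuple[str, dict | None, str]] = []
    if pm_row:
        bottom_rows.append(("P/M", None, "pm"))
    for rname in vm_rows:
        bottom_rows.append((rname, variant_meta.column(rname),
                            variant_meta.kind(rname)))
    for ri, (rname, column, kind) in enumerate(bottom_rows):
        yy = y0 + ri * opts.meta_cell_h
        if kind == "pm":
            for j in range(m):
                for k in range(2):
                    x, _, w, _ = canvas.cell_rect(0, canvas.display_col(j, k))
                    _fill(rgb, x, yy, w, opts.meta_cell_h,
                          PM_COLORS["P" if k == 0 else "M"])
            continue
        vids = data.variant_ids
        if kind == "numerical":
            vals = list(column.values())
            vmin, vmax = (min(vals), max(vals)) if vals else (0.0, 1.0)
            cmap = None
        else:
            cmap = category_color_map(
                [column.get(i) for i in vids if column.get(i)],
                opts.category_colors,
            )
            vmin = vmax = 0.0
        for j in range(m):
            color = meta_color(column.get(vids[j]), kind,
                               opts.numerical_gradient, vmin, vmax, cmap)
            x, _, _, _ = canvas.cell_rect(0, canvas.display_col(j, 0))
            _fill(rgb, x, yy, cols_per_variant * opts.cell_w,
                  opts.meta_cell_h, color)

    # --- identifier text ----------------------------------------------------
    if opts.show_subject_ids or opts.show_variant_ids:
        _draw_labels(canvas, data, opts, pm_row, y0 if pm_row else None)

    return canvas


def _base_color(code: int, variant, k: int, opts: RenderOptions,
                pair: tuple[int, int] | None = None) -> Color:
    if opts.encoding == "nucleotide":
        if code == MISSING_CODE:
            return opts.missing_color
        return cell_color_nucleotide(Allele(code), opts.nucleotide_palette)
    if opts.encoding == "reference":
        if code == MISSING_CODE:
            return opts.missing_color
        return cell_color_reference(
            Allele(code), variant.ref,
            opts.ref_match_color, opts.ref_mismatch_color, opts.missing_color,
        )
    a0, a1 = pair  # genotype encoding
    if MISSING_CODE in (a0, a1):
        return opts.missing_color
    return cell_color_genotype(
        Allele(a0), Allele(a1), variant.ref,
        opts.genotype_ref_color, opts.genotype_het_color,
        opts.genotype_hom_color, opts.missing_color,
    )


def _draw_subject_cells(rgb: np.ndarray, canvas: Canvas,
                        matrix: HaplotypeMatrix, opts: RenderOptions) -> None:
    calls = matrix.calls()
    for r in range(matrix.n_subjects):
        for j, v in enumerate(matrix.variants):
            if opts.encoding == "genotype":
                color = _base_color(0, v, 0, opts,
                                    pair=(int(calls[r, j, 0]), int(calls[r, j, 1])))
                x, y, w, h = canvas.cell_rect(r, canvas.display_col(j))
                _fill(rgb, x, y, w, h, color)
            else:
                for k in range(matrix.n_allele_columns):
                    color = _base_color(int(calls[r, j, k]), v, k, opts)
                    x, y, w, h = canvas.cell_rect(r, canvas.display_col(j, k))
                    _fill(rgb, x, y, w, h, color)


def _draw_aggregated_cells(rgb: np.ndarray, canvas: Canvas,
                           agg: AggregatedMatrix, opts: RenderOptions) -> None:
    for r in range(agg.n_groups):
        for j, v in enumerate(agg.variants):
            if opts.encoding == "genotype":
                pair = (int(agg.consensus[r, j, 0]), int(agg.consensus[r, j, 1]))
                color = _base_color(0, v, 0, opts, pair=pair)
                f = float(agg.frequency[r, j, :].mean())
                missing = MISSING_CODE in pair
                _draw_agg_cell(rgb, canvas, r, canvas.display_col(j),
                               color, f, missing, opts)
            else:
                for k in range(agg.n_allele_columns):
                    code = int(agg.consensus[r, j, k])
                    missing = code == MISSING_CODE
                    color = (opts.missing_color if missing
                             else _base_color(code, v, k, opts))
                    f = float(agg.frequency[r, j, k])
                    _draw_agg_cell(rgb, canvas, r, canvas.display_col(j, k),
                                   color, f, missing, opts)


def _draw_agg_cell(rgb: np.ndarray, canvas: Canvas, row: int, col: int,
                   color: Color, f: float, missing: bool,
                   opts: RenderOptions) -> None:
    x, y, w, h = canvas.cell_rect(row, col)
    if missing:
        _fill(rgb, x, y, w, h, opts.missing_color)
        return
    if opts.aggregate_mode == "saturation":
        _fill(rgb, x, y, w, h, _saturate(color, f, opts.saturation_floor))
        return
    f_disp = 1.0 - f if opts.rarity_bars else f
    bar = int(round(f_disp * h))
    _fill(rgb, x, y, w, h, WHITE)
    if bar > 0:
        _fill(rgb, x, y + h - bar, w, bar, color)


def _draw_labels(canvas: Canvas, data, opts: RenderOptions,
                 pm_row: bool, pm_y: int | None) -> None:
    img = Image.fromarray(canvas.rgb, mode="RGB")
    draw = ImageDraw.Draw(img)
    font = ImageFont.load_default()
    if opts.show_subject_ids and opts.cell_h >= 8:
        for r, lab in enumerate(canvas.row_labels):
            _, y, _, h = canvas.cell_rect(r, 0)
            draw.text((2, y + h // 2 - 5), lab[:11], fill=BLACK, font=font)
    if opts.show_variant_ids and opts.cell_w * canvas.cols_per_variant >= 8:
        for j, vid in enumerate(data.variant_ids):
            x, _, _, _ = canvas.cell_rect(0, canvas.display_col(j, 0))
            # vertical-ish: truncate to what fits the column block
            n_chars = max(1, (opts.cell_w * canvas.cols_per_variant) // 6)
            draw.text((x + 1, canvas.grid_y - 12), vid[:n_chars],
                      fill=BLACK, font=font)
    if pm_row and pm_y is not None and opts.cell_w >= 7 and opts.meta_cell_h >= 9:
        for j in range(data.n_variants):
            for k, letter in enumerate("PM"):
                x, _, w, _ = canvas.cell_rect(0, canvas.display_col(j, k))
                draw.text((x + w // 2 - 3, pm_y + opts.meta_cell_h // 2 - 5),
                          letter, fill=BLACK, font=font)
    canvas.rgb[:] = np.asarray(img)


# ---------------------------------------------------------------------------
# export

def export_image(
    canvas: Canvas,
    path: str | Path,
    format: str | None = None,
    dpi: int = 100,
    region: tuple[tuple[int, int], tuple[int, int]] | None = None,
) -> None:
    """Write the canvas to PNG/JPEG/TIFF (raster) or SVG/PDF (vector).

    *format* defaults to the file suffix.  *region* is an optional
    ((row_start, row_stop), (variant_start, variant_stop)) half-open range
    in data coordinates; only that part of the grid is exported.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "jpg":
        fmt = "jpeg"
    if fmt not in EXPORT_FORMATS:
        raise ValueError(
            f"unsupported export format {fmt!r}; choose one of {EXPORT_FORMATS}"
        )
    rgb = canvas.rgb
    if region is not None:
        (r0, r1), (j0, j1) = region
        x0, y0, _, _ = canvas.cell_rect(r0, canvas.display_col(j0, 0))
        x1 = canvas.grid_x + canvas.display_col(j1, 0) * canvas.cell_w
        y1 = canvas.grid_y + r1 * canvas.cell_h
        rgb = rgb[y0:y1, x0:x1]
        if rgb.size == 0:
            raise ValueError("empty export region")
    if fmt in ("png", "jpeg", "tiff"):
        img = Image.fromarray(rgb, mode="RGB")
        img.save(path, format=fmt.upper(), dpi=(dpi, dpi))
        return
    from matplotlib.figure import Figure

    h, w = rgb.shape[:2]
    fig = Figure(figsize=(w / dpi, h / dpi), dpi=dpi)
    ax = fig.add_axes([0, 0, 1, 1])
    ax.imshow(rgb, interpolation="nearest")
    ax.set_axis_off()
    fig.savefig(path, format=fmt, dpi=dpi)
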