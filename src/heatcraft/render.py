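"""Heatmap layout, rasterization and PNG/TIFF export.

The canvas is assembled from closed-form integer components so layout
arithmetic is exactly testable: margins, an optional vertical Y-axis title,
optional dendrogram gutters (left for rows, top for columns), the cell grid
itself, row labels on the right, column labels below (rotatable 0/45/90
degrees), an optional colorbar with original-scale min/max ticks, and an
optional X-axis title.  The raster origin is top-left with row 0 at the top,
matching spreadsheet reading order; cell rectangles are half-open so
adjacent cells share no pixels.

Figures are composed once at the 72 dpi reference scale; export resamples to
the requested resolution (nearest neighbor, preserving exact cell colors) so
pixel dimensions scale linearly with dpi at fixed physical size.  Canvas
sides are padded up to a multiple of 6 px, which makes the 72/300/600 dpi
presets land on exact integer scalings.  Text uses the font bundled with the
imaging library at a fixed size, and PNG/TIFF writing uses fixed settings
with no timestamps, so two exports of the same figure are byte-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from PIL import Image, ImageDraw, ImageFont

from . import cluster as _cluster
from .cluster import Dendrogram
from .colorscale import LUT_ROWS, ColorLUT, map_value
from .errors import FormatError, ValidationError
from .normalize import NormalizedMatrix
from .tabular_io import ExpressionTable

EXPORT_FORMATS = ("png", "tiff")

#: Conventional raster resolutions offered for figure export.
DPI_PRESETS = (72, 300, 600)

BASE_DPI = 72

_FONT = ImageFont.load_default(size=10)
_FONT_H = sum(_FONT.getmetrics())

DENDRO_DEPTH = 48
DENDRO_PAD = 4
LABEL_PAD = 4
TITLE_PAD = 6
CB_STRIP_W = 14
CB_PAD = 10

_BLACK = (0, 0, 0)
_WHITE = (255, 255, 255)


@dataclass(frozen=True)
class HeatmapSpec:
    """Geometry and decoration flags for one heatmap figure (pixels at 72 dpi)."""

    cell_w: int = 18
    cell_h: int = 18
    margins: tuple[int, int, int, int] = (12, 12, 12, 12)  # top, right, bottom, left
    transpose: bool = False
    rotate_labels: int = 0  # column-label angle: 0, 45 or 90 degrees
    show_row_dendrogram: bool = True
    show_col_dendrogram: bool = True
    show_colorbar: bool = True
    x_title: str = ""
    y_title: str = ""

    def __post_init__(self) -> None:
        if self.cell_w < 1 or self.cell_h < 1:
            raise ValidationError("cell_w and cell_h must be >= 1 pixel")
        if any(m < 0 for m in self.margins):
            raise ValidationError("margins must be non-negative")
        if self.rotate_labels not in (0, 45, 90):
            raise ValidationError(
                f"rotate_labels must be 0, 45 or 90, got {self.rotate_labels}"
            )


@dataclass
class RenderedFigure:
    """The composed raster plus per-cell pixel rectangles (half-open, x0,y0,x1,y1)."""

    raster: np.ndarray
    dpi: int
    cell_boxes: np.ndarray


def _text_w(text: str) -> int:
    return _FONT.getbbox(text)[2] if text else 0


def _label_image(text: str, angle: int) -> Image.Image:
    """Render one label on a transparent tile, rotated by ``angle`` degrees."""
    w = max(_text_w(text), 1)
    tile = Image.new("RGBA", (w, _FONT_H), (0, 0, 0, 0))
    ImageDraw.Draw(tile).text((0, 0), text, fill=(0, 0, 0, 255), font=_FONT)
    if angle:
        tile = tile.rotate(angle, expand=True, resample=Image.NEAREST)
    return tile


def _col_label_extent(labels: list[str], angle: int) -> int:
    if not labels:
        return 0
    if angle == 0:
        return _FONT_H
    return max(_label_image(lab, angle).height for lab in labels)


@dataclass
class Layout:
    """Closed-form component sizes; total canvas = the sum of each direction."""

    # horizontal components, left to right
    margin_left: int
    y_title_w: int
    row_dendro_w: int
    heatmap_w: int
    row_label_w: int
    colorbar_w: int
    margin_right: int
    pad_x: int
    # vertical components, top to bottom
    margin_top: int
    col_dendro_h: int
    heatmap_h: int
    col_label_h: int
    x_title_h: int
    margin_bottom: int
    pad_y: int

    @property
    def total_w(self) -> int:
        return (
            self.margin_left + self.y_title_w + self.row_dendro_w + self.heatmap_w
            + self.row_label_w + self.colorbar_w + self.margin_right + self.pad_x
        )

    @property
    def total_h(self) -> int:
        return (
            self.margin_top + self.col_dendro_h + self.heatmap_h + self.col_label_h
            + self.x_title_h + self.margin_bottom + self.pad_y
        )

    @property
    def heat_x0(self) -> int:
        return self.margin_left + self.y_title_w + self.row_dendro_w

    @property
    def heat_y0(self) -> int:
        return self.margin_top + self.col_dendro_h


def _colorbar_labels(nm: NormalizedMatrix) -> list[str]:
    labels = [f"{nm.ov_max:g}", f"{nm.ov_min:g}"]
    if nm.spec.mode == "log":
        base = nm.spec.base_a
        labels.append("ln" if abs(base - np.e) < 1e-12 else f"log{base:g}")
    return labels


def compute_layout(
    n_rows: int,
    n_cols: int,
    spec: HeatmapSpec,
    row_labels: list[str],
    col_labels: list[str],
    nm: NormalizedMatrix,
    has_row_tree: bool,
    has_col_tree: bool,
) -> Layout:
    """Component sizes for the displayed (post-transpose) matrix."""
    top, right, bottom, left = spec.margins
    y_title_w = (_FONT_H + TITLE_PAD) if spec.y_title else 0
    x_title_h = (_FONT_H + TITLE_PAD) if spec.x_title else 0
    row_dendro_w = (DENDRO_DEPTH + DENDRO_PAD) if (has_row_tree and spec.show_row_dendrogram) else 0
    col_dendro_h = (DENDRO_DEPTH + DENDRO_PAD) if (has_col_tree and spec.show_col_dendrogram) else 0
    heatmap_w = n_cols * spec.cell_w
    heatmap_h = n_rows * spec.cell_h
    row_label_w = (LABEL_PAD + max(_text_w(lab) for lab in row_labels)) if row_labels else 0
    col_label_h = LABEL_PAD + _col_label_extent(col_labels, spec.rotate_labels) if col_labels else 0
    if spec.show_colorbar:
        colorbar_w = CB_PAD + CB_STRIP_W + LABEL_PAD + max(
            _text_w(lab) for lab in _colorbar_labels(nm)
        )
    else:
        colorbar_w = 0
    w = left + y_title_w + row_dendro_w + heatmap_w + row_label_w + colorbar_w + right
    h = top + col_dendro_h + heatmap_h + col_label_h + x_title_h + bottom
    # Pad to a multiple of 6 so the 72/300/600 dpi presets scale exactly.
    pad_x = (-w) % 6
    pad_y = (-h) % 6
    return Layout(
        margin_left=left, y_title_w=y_title_w, row_dendro_w=row_dendro_w,
        heatmap_w=heatmap_w, row_label_w=row_label_w, colorbar_w=colorbar_w,
        margin_right=right, pad_x=pad_x,
        margin_top=top, col_dendro_h=col_dendro_h, heatmap_h=heatmap_h,
        col_label_h=col_label_h, x_title_h=x_title_h, margin_bottom=bottom,
        pad_y=pad_y,
    )


def _node_positions(tree: Dendrogram, centers: list[int]) -> dict[int, float]:
    """Along-axis position of every tree node: leaves at their displayed cell
    centers, internal nodes at the midpoint of their children."""
    order = _cluster.leaf_order(tree)
    pos: dict[int, float] = {leaf: float(centers[slot]) for slot, leaf in enumerate(order)}
    for i, (left, right, _h) in enumerate(tree.merges):
        pos[tree.n_leaves + i] = (pos[left] + pos[right]) / 2.0
    return pos


def _draw_row_dendrogram(
    draw: ImageDraw.ImageDraw, tree: Dendrogram, x0: int, x1: int, centers: list[int]
) -> None:
    max_h = max(tree.height(tree.root), 1e-300)
    depth = x1 - x0 - 1

    def hx(h: float) -> int:
        return x1 - 1 - round(h / max_h * depth)

    pos = _node_positions(tree, centers)
    for left, right, h in tree.merges:
        x = hx(h)
        yl, yr = round(pos[left]), round(pos[right])
        draw.line([(x, yl), (x, yr)], fill=_BLACK)
        for child, yc in ((left, yl), (right, yr)):
            draw.line([(x, yc), (hx(tree.height(child)), yc)], fill=_BLACK)


def _draw_col_dendrogram(
    draw: ImageDraw.ImageDraw, tree: Dendrogram, y0: int, y1: int, centers: list[int]
) -> None:
    max_h = max(tree.height(tree.root), 1e-300)
    depth = y1 - y0 - 1

    def hy(h: float) -> int:
        return y1 - 1 - round(h / max_h * depth)

    pos = _node_positions(tree, centers)
    for left, right, h in tree.merges:
        y = hy(h)
        xl, xr = round(pos[left]), round(pos[right])
        draw.line([(xl, y), (xr, y)], fill=_BLACK)
        for child, xc in ((left, xl), (right, xr)):
            draw.line([(xc, y), (xc, hy(tree.height(child)))], fill=_BLACK)


def compose(
    table: ExpressionTable,
    nm: NormalizedMatrix,
    lut: ColorLUT,
    spec: HeatmapSpec,
    row_tree: Dendrogram | None = None,
    col_tree: Dendrogram | None = None,
) -> RenderedFigure:
    """Assemble the full figure at the 72 dpi reference scale.

    Rows/columns are permuted by the dendrogram leaf orders when trees are
    given; the transpose flag then swaps the displayed axes, titles and
    dendrogram gutters.
    """
    if nm.shape != table.shape:
        raise ValidationError(
            f"normalized matrix shape {nm.shape} does not match table {table.shape}"
        )
    r, c = table.shape
    if row_tree is not None and row_tree.n_leaves != r:
        raise ValidationError(
            f"row tree has {row_tree.n_leaves} leaves for {r} rows"
        )
    if col_tree is not None and col_tree.n_leaves != c:
        raise ValidationError(
            f"column tree has {col_tree.n_leaves} leaves for {c} columns"
        )

    nv = nm.values
    row_labels = list(table.row_labels)
    col_labels = list(table.col_labels)
    if row_tree is not None:
        order = _cluster.leaf_order(row_tree)
        nv = nv[order, :]
        row_labels = [row_labels[i] for i in order]
    if col_tree is not None:
        order = _cluster.leaf_order(col_tree)
        nv = nv[:, order]
        col_labels = [col_labels[j] for j in order]

    x_title, y_title = spec.x_title, spec.y_title
    if spec.transpose:
        nv = nv.T
        row_labels, col_labels = col_labels, row_labels
        row_tree, col_tree = col_tree, row_tree
        x_title, y_title = y_title, x_title
    n_rows, n_cols = nv.shape

    layout = compute_layout(
        n_rows, n_cols,
        dataclasses.replace(spec, x_title=x_title, y_title=y_title),
        row_labels, col_labels, nm,
        has_row_tree=row_tree is not None,
        has_col_tree=col_tree is not None,
    )
    img = Image.new("RGB", (layout.total_w, layout.total_h), _WHITE)
    draw = ImageDraw.Draw(img)
    hx0, hy0 = layout.heat_x0, layout.heat_y0

    cell_boxes = np.empty((n_rows, n_cols, 4), dtype=int)
    for i in range(n_rows):
        for j in range(n_cols):
            x0 = hx0 + j * spec.cell_w
            y0 = hy0 + i * spec.cell_h
            x1, y1 = x0 + spec.cell_w, y0 + spec.cell_h
            cell_boxes[i, j] = (x0, y0, x1, y1)
            draw.rectangle([x0, y0, x1 - 1, y1 - 1], fill=map_value(float(nv[i, j]), lut))

    row_centers = [hy0 + i * spec.cell_h + spec.cell_h // 2 for i in range(n_rows)]
    col_centers = [hx0 + j * spec.cell_w + spec.cell_w // 2 for j in range(n_cols)]

    # Row labels, right of the grid, vertically centered per row.
    lx = hx0 + layout.heatmap_w + LABEL_PAD
    for i, lab in enumerate(row_labels):
        if lab:
            draw.text((lx, row_centers[i] - _FONT_H // 2), lab, fill=_BLACK, font=_FONT)

    # Column labels below the grid.
    ly = hy0 + layout.heatmap_h + LABEL_PAD
    for j, lab in enumerate(col_labels):
        if not lab:
            continue
        tile = _label_image(lab, spec.rotate_labels)
        if spec.rotate_labels == 0:
            img.paste(tile, (col_centers[j] - tile.width // 2, ly), tile)
        else:
            # rotated labels hang from their top-right corner under the column
            img.paste(tile, (col_centers[j] - tile.width + _FONT_H // 2, ly), tile)

    if row_tree is not None and spec.show_row_dendrogram:
        gx0 = layout.margin_left + layout.y_title_w
        _draw_row_dendrogram(draw, row_tree, gx0, gx0 + DENDRO_DEPTH, row_centers)
    if col_tree is not None and spec.show_col_dendrogram:
        gy0 = layout.margin_top
        _draw_col_dendrogram(draw, col_tree, gy0, gy0 + DENDRO_DEPTH, col_centers)

    if spec.show_colorbar:
        cbx = hx0 + layout.heatmap_w + layout.row_label_w + CB_PAD
        cby0, cby1 = hy0, hy0 + layout.heatmap_h
        span = max(cby1 - 1 - cby0, 1)
        for y in range(cby0, cby1):
            frac = 1.0 - (y - cby0) / span
            row = lut.rows[int(frac * (LUT_ROWS - 1) + 0.5)]
            draw.line([(cbx, y), (cbx + CB_STRIP_W - 1, y)], fill=tuple(int(v) for v in row))
        labels = _colorbar_labels(nm)
        tx = cbx + CB_STRIP_W + LABEL_PAD
        draw.text((tx, cby0), labels[0], fill=_BLACK, font=_FONT)
        draw.text((tx, cby1 - _FONT_H), labels[1], fill=_BLACK, font=_FONT)
        if len(labels) > 2:
            draw.text((tx, (cby0 + cby1) // 2 - _FONT_H // 2), labels[2], fill=_BLACK, font=_FONT)

    if x_title:
        ty = hy0 + layout.heatmap_h + layout.col_label_h + TITLE_PAD
        draw.text((hx0 + (layout.heatmap_w - _text_w(x_title)) // 2, ty),
                  x_title, fill=_BLACK, font=_FONT)
    if y_title:
        tile = _label_image(y_title, 90)
        img.paste(tile, (layout.margin_left,
                         hy0 + (layout.heatmap_h - tile.height) // 2), tile)

    return RenderedFigure(raster=np.asarray(img), dpi=BASE_DPI, cell_boxes=cell_boxes)


def export(
    fig: RenderedFigure, path, format: str = "png", dpi: int = 300
) -> None:
    """Write the figure as PNG or TIFF with dpi metadata.

    The physical size is fixed by the 72 dpi composition, so pixel dimensions
    scale linearly with the requested dpi (exactly for the 72/300/600
    presets).  TIFF is uncompressed and PNG uses a fixed compression level;
    neither carries timestamps, so repeated exports are byte-identical.
    """
    if format not in EXPORT_FORMATS:
        raise ValidationError(
            f"unsupported format {format!r}; expected one of {', '.join(EXPORT_FORMATS)}"
        )
    if not (isinstance(dpi, int) and dpi > 0):
        raise ValidationError(f"dpi must be a positive integer, got {dpi!r}")
    img = Image.fromarray(fig.raster)
    if dpi != fig.dpi:
        w = round(img.width * dpi / fig.dpi)
        h = round(img.height * dpi / fig.dpi)
        img = img.resize((w, h), Image.NEAREST)
    try:
        if format == "png":
            img.save(path, format="PNG", dpi=(dpi, dpi), compress_level=6)
        else:
            img.save(path, format="TIFF", dpi=(dpi, dpi), compression=None)
    except OSError as exc:
        raise FormatError(f"cannot write {path}: {exc}") from exc
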