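"""Printed and handwritten-style text overlays with ground-truth ink masks.

Printed lead names and metadata use an ordinary font; handwritten-style
keywords are produced by rendering a base font and perturbing it per style
(per-character rotation jitter, a sinusoidal baseline, slant and thickness),
giving seven deterministic presets in place of a learned handwriting model.
Every overlay records the exact set of pixels it inked.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
from PIL import Image, ImageDraw, ImageFont
from scipy import ndimage

from .errors import ParameterError
from .paper_render import GroundTruth, PaperImage

N_HANDWRITING_STYLES = 7

# (slant shear, baseline wave amplitude px/size, wave length px, per-char
#  rotation jitter deg, extra thickness iters, ink RGB)
_STYLES = (
    (0.15, 0.08, 90.0, 4.0, 0, (20, 20, 90)),
    (-0.10, 0.12, 70.0, 6.0, 0, (10, 10, 10)),
    (0.30, 0.05, 120.0, 3.0, 1, (25, 25, 120)),
    (0.00, 0.15, 60.0, 8.0, 0, (15, 15, 60)),
    (0.22, 0.10, 80.0, 5.0, 1, (0, 0, 0)),
    (-0.20, 0.07, 100.0, 7.0, 0, (30, 30, 100)),
    (0.10, 0.18, 50.0, 10.0, 1, (10, 10, 40)),
)


@dataclass
class TextOverlay:
    """One piece of overlaid text and the pixels it inked."""

    text: str
    kind: str                      # "printed" | "handwritten"
    anchor: tuple                  # (col, row)
    mask: np.ndarray               # bool, same H x W as the target image
    style_id: int = -1             # valid for handwritten only


def _font(size: int):
    try:
        return ImageFont.load_default(size=size)
    except TypeError:  # pragma: no cover - older Pillow
        return ImageFont.load_default()


def _text_mask(text: str, size: int) -> np.ndarray:
    """Rasterize ``text`` to a tight boolean glyph mask."""
    font = _font(size)
    probe = Image.new("L", (1, 1))
    bbox = ImageDraw.Draw(probe).textbbox((0, 0), text, font=font)
    w = max(1, bbox[2] - bbox[0] + 2)
    h = max(1, bbox[3] - bbox[1] + 2)
    canvas = Image.new("L", (w, h), 0)
    ImageDraw.Draw(canvas).text((1 - bbox[0], 1 - bbox[1]), text, fill=255,
                                font=font)
    return np.asarray(canvas) > 96


def _paste_mask(full: np.ndarray, local: np.ndarray, row: int, col: int) -> None:
    h, w = full.shape
    lh, lw = local.shape
    r0, c0 = max(row, 0), max(col, 0)
    r1, c1 = min(row + lh, h), min(col + lw, w)
    if r1 <= r0 or c1 <= c0:
        return
    full[r0:r1, c0:c1] |= local[r0 - row:r1 - row, c0 - col:c1 - col]


def _apply_ink(image: PaperImage, mask: np.ndarray, color) -> PaperImage:
    out = image.copy()
    px = out.pixels.copy()
    px[mask] = np.array(color, dtype=np.uint8)
    out.pixels = px
    return out


def _trace_raster(ground_truth: GroundTruth, shape) -> np.ndarray:
    """Boolean raster of all ground-truth polyline pixels (jumps included)."""
    h, w = shape
    trace = np.zeros((h, w), dtype=bool)
    for seg in ground_truth.all_segments():
        cols = np.round(seg.cols).astype(int)
        rows = np.round(seg.rows).astype(int)
        ok = (cols >= 0) & (cols < w) & (rows >= 0) & (rows < h)
        trace[rows[ok], cols[ok]] = True
        for i in range(1, len(cols)):
            if 0 <= cols[i] < w and abs(rows[i] - rows[i - 1]) > 1:
                lo, hi = sorted((rows[i - 1], rows[i]))
                trace[max(lo, 0):min(hi + 1, h), cols[i]] = True
    return trace


def overlay_lead_names(image: PaperImage, ground_truth: GroundTruth,
                       font_size: int = 18, color=(0, 0, 0),
                       allow_trace_overlap: bool = True):
    """Print one lead label near the start of every rendered segment.

    Returns ``(image', overlays)``.  With ``allow_trace_overlap=False`` each
    label is nudged upward until its ink is disjoint from every trace pixel.
    """
    h, w = image.shape
    trace = None
    if not allow_trace_overlap:
        trace = _trace_raster(ground_truth, (h, w))
    overlays = []
    out = image.copy()
    for seg in ground_truth.segments:
        local = _text_mask(seg.lead, font_size)
        col = int(np.round(seg.cols[0])) + 3
        row = int(seg.baseline_row) - int(2.2 * font_size)
        if trace is not None:
            for _ in range(h):
                probe = np.zeros((h, w), dtype=bool)
                _paste_mask(probe, local, row, col)
                if not np.any(probe & trace):
                    break
                row -= 2
        mask = np.zeros((h, w), dtype=bool)
        _paste_mask(mask, local, row, col)
        out = _apply_ink(out, mask, color)
        overlays.append(TextOverlay(seg.lead, "printed", (col, row), mask))
    if overlays:
        out.log("overlay_lead_names", n=len(overlays), font_size=font_size)
    return out, overlays


def overlay_printed_metadata(image: PaperImage, header_or_template,
                             header: dict = None, anchor=(10, 8),
                             font_size: int = 16, color=(0, 0, 0)):
    """Render header fields (or a ``{field}``-template) as a printed block.

    ``header_or_template`` is either a metadata dict (one ``key: value`` line
    per non-empty field) or a template string formatted against ``header``;
    a template naming an unknown field raises :class:`ParameterError`.
    Returns ``(image', overlays)``.
    """
    if isinstance(header_or_template, dict):
        lines = [f"{k}: {v}" for k, v in header_or_template.items() if str(v)]
    else:
        header = header or {}
        try:
            text = str(header_or_template).format(**header)
        except KeyError as exc:
            raise ParameterError(f"template references unknown field "
                                 f"{exc.args[0]!r}") from None
        lines = [ln for ln in text.splitlines() if ln.strip()] or (
            [text] if text.strip() else [])
    if not lines:
        return image.copy(), []
    h, w = image.shape
    out = image.copy()
    overlays = []
    col, row = int(anchor[0]), int(anchor[1])
    for line in lines:
        local = _text_mask(line, font_size)
        mask = np.zeros((h, w), dtype=bool)
        _paste_mask(mask, local, row, col)
        out = _apply_ink(out, mask, color)
        overlays.append(TextOverlay(line, "printed", (col, row), mask))
        row += int(1.4 * font_size)
    out.log("overlay_printed_metadata", n_lines=len(lines))
    return out, overlays


def load_lexicon(path: str = None) -> list:
    """Load a keyword lexicon (UTF-8, one phrase per line)."""
    if path is None:
        text = (resources.files("ecgpaper") / "data" / "keywords.txt").read_text()
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    return [ln.strip() for ln in text.splitlines() if ln.strip()]


def sample_keywords(lexicon, n: int, seed: int = 0) -> list:
    """Draw ``n`` keywords, without replacement while possible."""
    lexicon = list(lexicon)
    if n < 0:
        raise ParameterError("n must be >= 0")
    if n == 0:
        return []
    if not lexicon:
        raise ParameterError("empty lexicon")
    rng = np.random.default_rng(seed)
    if n <= len(lexicon):
        idx = rng.choice(len(lexicon), size=n, replace=False)
    else:
        idx = np.concatenate([rng.permutation(len(lexicon)),
                              rng.choice(len(lexicon), size=n - len(lexicon))])
    return [lexicon[i] for i in idx]


def _handwritten_mask(text: str, style_id: int, size: int,
                      rng: np.random.Generator) -> np.ndarray:
    slant, wave_amp, wave_len, jitter, thick, _ = _STYLES[style_id]
    pad = size
    glyphs = []
    for ch in text:
        if ch == " ":
            glyphs.append(None)
            continue
        g = _text_mask(ch, size)
        angle = rng.normal(0.0, jitter)
        g = ndimage.rotate(g.astype(float), angle, order=1, reshape=True) > 0.5
        glyphs.append(g)
    width = sum((g.shape[1] if g is not None else size // 2) + 1
                for g in glyphs) + 2 * pad
    height = 2 * size + 2 * pad
    canvas = np.zeros((height, width), dtype=bool)
    x = pad
    base_row = height // 2
    phase = rng.uniform(0, 2 * np.pi)
    for g in glyphs:
        if g is None:
            x += size // 2 + 1
            continue
        dy = int(round(wave_amp * size * np.sin(2 * np.pi * x / wave_len + phase)))
        _paste_mask(canvas, g, base_row - g.shape[0] // 2 + dy, x)
        x += g.shape[1] + 1
    if abs(slant) > 1e-9:
        sheared = np.zeros_like(canvas)
        for r in range(height):
            shift = int(round(slant * (base_row - r)))
            src = canvas[r]
            if shift >= 0:
                sheared[r, shift:] = src[:width - shift] if shift else src
            else:
                sheared[r, :width + shift] = src[-shift:]
        canvas = sheared
    if thick:
        canvas = ndimage.binary_dilation(canvas, iterations=thick)
    rows = np.any(canvas, axis=1)
    cols = np.any(canvas, axis=0)
    if not rows.any():
        return np.zeros((1, 1), dtype=bool)
    r0, r1 = np.nonzero(rows)[0][[0, -1]]
    c0, c1 = np.nonzero(cols)[0][[0, -1]]
    return canvas[r0:r1 + 1, c0:c1 + 1]


def render_handwritten(image: PaperImage, text: str, style_id: int = 0,
                       anchor=None, seed: int = 0, size: int = 22):
    """Overlay ``text`` in one of the seven handwriting-style presets.

    ``anchor=None`` picks a uniform-random in-bounds placement from ``seed``.
    Returns ``(image', overlay)``; empty text is a no-op.
    """
    if not 0 <= style_id < N_HANDWRITING_STYLES:
        raise ParameterError("style_id must be in 0..6")
    if not text:
        return image.copy(), None
    rng = np.random.default_rng(seed)
    local = _handwritten_mask(text, style_id, size, rng)
    h, w = image.shape
    lh, lw = local.shape
    if anchor is None:
        col = int(rng.integers(0, max(1, w - lw)))
        row = int(rng.integers(0, max(1, h - lh)))
    else:
        col, row = int(anchor[0]), int(anchor[1])
        if not (0 <= col < w and 0 <= row < h):
            raise ParameterError("anchor outside image")
    mask = np.zeros((h, w), dtype=bool)
    _paste_mask(mask, local, row, col)
    out = _apply_ink(image, mask, _STYLES[style_id][5])
    out.log("render_handwritten", text=text, style_id=style_id, seed=seed)
    return out, TextOverlay(text, "handwritten", (col, row), mask, style_id)
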