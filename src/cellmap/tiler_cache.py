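"""Tile slicing and the file-system tile cache (step 4).

Each level raster is sliced into fixed-size tiles (400x200 pixels by
default, the size used for slippy-map delivery).  Edge tiles are padded
with the background color so every tile has identical dimensions.  Tiles
are addressed ``(organism, zoom, col, row)`` and persisted under::

    root/<organism>/<stamp>/<zoom>/<col>_<row>.<ext>

The content stamp of the organism's network is embedded in the path, so
invalidation is atomic: a modified network gets a fresh stamp directory
and the stale tree can simply be deleted.  Tiles are regenerated only
when the stamp changes; a cache hit performs no rendering.  On a miss the
whole level is rendered and sliced at once (the per-level pipeline
amortizes rendering across that level's tiles).
"""

from __future__ import annotations

import math
import shutil
from pathlib import Path
from typing import Callable, Optional, Union

from PIL import Image
from pydantic import BaseModel

TILE_W = 400
TILE_H = 200


class TileAddress(BaseModel):
    organism_id: str
    zoom: int
    col: int
    row: int


class Tile(BaseModel):
    model_config = {"arbitrary_types_allowed": True}

    address: TileAddress
    image: Image.Image

    @property
    def size(self) -> tuple[int, int]:
        return self.image.size


class TileAddressError(ValueError):
    def __init__(self, addr: TileAddress, n_cols: int, n_rows: int):
        super().__init__(
            f"tile ({addr.col}, {addr.row}) out of range for zoom {addr.zoom}: "
            f"valid cols 0..{n_cols - 1}, rows 0..{n_rows - 1}"
        )


def tile_grid(width: int, height: int, tile_w: int = TILE_W, tile_h: int = TILE_H) -> tuple[int, int]:
    """(n_cols, n_rows) covering a raster of the given size."""
    return math.ceil(width / tile_w), math.ceil(height / tile_h)


def slice_tiles(
    img: Image.Image,
    tile_w: int = TILE_W,
    tile_h: int = TILE_H,
    organism_id: str = "",
    zoom: int = 0,
    background: tuple[int, int, int] = (255, 255, 255),
) -> list[Tile]:
    """Slice a level raster into tiles covering it exactly once.

    Tile (c, r) holds pixels [c*tile_w, (c+1)*tile_w) x [r*tile_h,
    (r+1)*tile_h); pixels beyond the raster edge are background-padded so
    every tile is exactly tile_w x tile_h.
    """
    if tile_w <= 0 or tile_h <= 0:
        raise ValueError("tile dimensions must be positive")
    W, H = img.size
    n_cols, n_rows = tile_grid(W, H, tile_w, tile_h)
    tiles: list[Tile] = []
    for r in range(n_rows):
        for c in range(n_cols):
            x0, y0 = c * tile_w, r * tile_h
            x1, y1 = min(x0 + tile_w, W), min(y0 + tile_h, H)
            piece = img.crop((x0, y0, x1, y1))
            if piece.size != (tile_w, tile_h):
                padded = Image.new("RGB", (tile_w, tile_h), background)
                padded.paste(piece, (0, 0))
                piece = padded
            tiles.append(
                Tile(
                    address=TileAddress(organism_id=organism_id, zoom=zoom, col=c, row=r),
                    image=piece,
                )
            )
    return tiles


def reassemble(tiles: list[Tile], width: int, height: int, tile_w: int = TILE_W, tile_h: int = TILE_H) -> Image.Image:
    """Mosaic tiles back into a raster, cropped to the original bounds."""
    out = Image.new("RGB", (width, height))
    for t in tiles:
        out.paste(t.image, (t.address.col * tile_w, t.address.row * tile_h))
    return out


class TileCache:
    """Disk cache of encoded tiles keyed by organism, stamp, zoom, position.

    ``pipeline`` arguments are closures ``zoom -> PIL.Image`` that render
    the full level raster; they are only invoked on a miss.
    """

    def __init__(
        self,
        root: Union[str, Path],
        tile_w: int = TILE_W,
        tile_h: int = TILE_H,
        fmt: str = "PNG",
    ):
        self.root = Path(root)
        self.tile_w = tile_w
        self.tile_h = tile_h
        self.fmt = fmt.upper()
        self.ext = {"PNG": "png", "GIF": "gif"}[self.fmt]

    # -- paths ---------------------------------------------------------------

    def organism_dir(self, organism_id: str, stamp: str) -> Path:
        return self.root / organism_id / stamp

    def level_dir(self, organism_id: str, stamp: str, zoom: int) -> Path:
        return self.organism_dir(organism_id, stamp) / str(zoom)

    def tile_path(self, addr: TileAddress, stamp: str) -> Path:
        return self.level_dir(addr.organism_id, stamp, addr.zoom) / f"{addr.col}_{addr.row}.{self.ext}"

    # -- level operations -----------------------------------------------------

    def level_is_cached(self, organism_id: str, stamp: str, zoom: int) -> bool:
        return (self.level_dir(organism_id, stamp, zoom) / "DONE").exists()

    def store_level(self, organism_id: str, stamp: str, zoom: int, img: Image.Image,
                    background: tuple[int, int, int] = (255, 255, 255)) -> list[Path]:
        """Slice a rendered level and persist all of its tiles."""
        self.invalidate_stale(organism_id, stamp)
        level_dir = self.level_dir(organism_id, stamp, zoom)
        level_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for tile in slice_tiles(img, self.tile_w, self.tile_h, organism_id, zoom, background):
            p = self.tile_path(tile.address, stamp)
            tile.image.save(p, self.fmt)
            paths.append(p)
        (level_dir / "SIZE").write_text(f"{img.size[0]}\t{img.size[1]}")
        (level_dir / "DONE").write_text("")
        return paths

    def level_size(self, organism_id: str, stamp: str, zoom: int) -> tuple[int, int]:
        w, h = (self.level_dir(organism_id, stamp, zoom) / "SIZE").read_text().split("\t")
        return int(w), int(h)

    def invalidate_stale(self, organism_id: str, stamp: str) -> None:
        """Drop stamp directories other than the current one."""
        org_root = self.root / organism_id
        if not org_root.is_dir():
            return
        for d in org_root.iterdir():
            if d.is_dir() and d.name != stamp:
                shutil.rmtree(d)

    # -- tile access -----------------------------------------------------------

    def get_tile(
        self,
        addr: TileAddress,
        stamp: str,
        pipeline: Callable[[int], Image.Image],
        background: tuple[int, int, int] = (255, 255, 255),
    ) -> bytes:
        """Encoded tile bytes; renders the whole level on a cache miss.

        A stale stamp invalidates the organism's previous cache tree.
        Out-of-bounds addresses raise :class:`TileAddressError` with the
        valid ranges.
        """
        self.invalidate_stale(addr.organism_id, stamp)
        if not self.level_is_cached(addr.organism_id, stamp, addr.zoom):
            img = pipeline(addr.zoom)
            self.store_level(addr.organism_id, stamp, addr.zoom, img, background)
        W, H = self.level_size(addr.organism_id, stamp, addr.zoom)
        n_cols, n_rows = tile_grid(W, H, self.tile_w, self.tile_h)
        if not (0 <= addr.col < n_cols and 0 <= addr.row < n_rows):
            raise TileAddressError(addr, n_cols, n_rows)
        return self.tile_path(addr, stamp).read_bytes()

    def url_template(self) -> str:
        """Tile URL pattern for a static file server over ``root``."""
        return "{root}/{organism}/{stamp}/{zoom}/{col}_{row}." + self.ext
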