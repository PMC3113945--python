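"""End-to-end map publication pipeline shared by the CLI and scripts.

``build_map`` runs the four base-image steps for every zoom level through
the stamp-keyed tile cache, then emits the node/frame data bundle.  The
returned :class:`BuildResult` exposes render/cache-hit counters so cache
purity is observable (a rebuild of an unmodified organism must render
nothing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from PIL import Image

from .layout_engine import LayoutConfig, MasterLayout, layout_master
from .locator import build_frame_data, build_node_data, export_client_data
from .network_model import PGDB
from .tiler_cache import TileCache
from .zoom_renderer import (
    RenderStats,
    StyleConfig,
    ZoomLayout,
    render_image,
    specialize_layout,
)


@dataclass
class BuildResult:
    pgdb: PGDB
    master: MasterLayout
    cache: TileCache
    style: StyleConfig
    renders: int = 0
    cache_hits: int = 0
    zoom_layouts: dict[int, ZoomLayout] = field(default_factory=dict)
    data_files: list[Path] = field(default_factory=list)

    def level_image(self, level: int) -> Image.Image:
        """Reassemble a level raster from cached tiles (no rendering)."""
        from .tiler_cache import Tile, TileAddress, reassemble

        stamp = self.pgdb.version_stamp
        W, H = self.cache.level_size(self.pgdb.organism_id, stamp, level)
        tiles = []
        for p in sorted(
            self.cache.level_dir(self.pgdb.organism_id, stamp, level).glob(
                f"*.{self.cache.ext}"
            )
        ):
            col, row = p.stem.split("_")
            tiles.append(
                Tile(
                    address=TileAddress(
                        organism_id=self.pgdb.organism_id,
                        zoom=level,
                        col=int(col),
                        row=int(row),
                    ),
                    image=Image.open(p).convert("RGB"),
                )
            )
        return reassemble(tiles, W, H, self.cache.tile_w, self.cache.tile_h)


def build_map(
    pgdb: PGDB,
    outdir: Union[str, Path],
    style: Optional[StyleConfig] = None,
    layout_cfg: Optional[LayoutConfig] = None,
    master: Optional[MasterLayout] = None,
) -> BuildResult:
    """Layout + per-level render/slice (cache-aware) + client data bundle."""
    outdir = Path(outdir)
    style = style or StyleConfig()
    master = master or layout_master(pgdb, layout_cfg)
    master_path = outdir / f"{pgdb.organism_id}.layout.json"
    outdir.mkdir(parents=True, exist_ok=True)
    master.save(master_path)
    cache = TileCache(outdir / "tiles")
    stats = RenderStats()
    result = BuildResult(pgdb=pgdb, master=master, cache=cache, style=style)
    stamp = pgdb.version_stamp
    node_data = {}
    for level in range(style.n_levels):
        zl = specialize_layout(master, level, style)
        result.zoom_layouts[level] = zl
        if cache.level_is_cached(pgdb.organism_id, stamp, level):
            result.cache_hits += 1
        else:
            img = render_image(zl, style, stats)
            cache.store_level(pgdb.organism_id, stamp, level, img, style.background)
        node_data[level] = build_node_data(zl)
    result.renders = stats.renders
    frame_data = build_frame_data(pgdb)
    result.data_files = export_client_data(node_data, frame_data, outdir / "data")
    return result
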