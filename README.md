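# cellmap

Batch toolkit for generating **organism-specific, zoomable, tiled
metabolic-map diagrams** (whole-cell overview style) from a metabolic
network description, with entity search/highlight overlays, tooltip
data, and painting of omics datasets onto the map.

It is aimed at people who publish or serve whole-cell metabolic maps:
given a network (pathways, reactions, compounds, enzymes, genes,
compartments), `cellmap` produces everything a slippy-map client needs
as static files — a tile pyramid, clickable-geometry indexes, tooltip
text, and overlay documents — with no server-side rendering at view
time.

## What it computes

**Layout.** A deterministic, zoom-independent *master layout* places
every drawable object once, following the standard conventions of the
diagram: horizontal bands for extracellular space, outer membrane,
periplasm, inner membrane, and cytoplasm; central metabolism
(glycolysis/TCA-type pathways) in the middle column separating
catabolic pathways (right) from anabolic/intermediary pathways (left);
signal-transduction pathways along the bottom left; reactions assigned
to no pathway in a rectangular grid at the far right; transporters
embedded in their membrane band; pathways grouped into shaded cluster
boxes and flowing downward. Metabolites are drawn locally per reaction
(duplicated across pathways) because drawing the network's true
connectivity as edges would make an organism-scale diagram unreadable.

**Semantic zoom.** Six zoom levels, scale halving per level. Higher
levels reveal *more object classes*, not just bigger pixels: enzymes
are absent at the lowest level; pathway, compound, enzyme/gene names
and EC numbers switch on progressively, and any label that does not fit
is dropped, never truncated. Each level is rasterized to one large
image and sliced into 400×200 tiles, cached on the file system keyed by
a content hash of the network — tiles are regenerated only when the
network changes.

**Search.** Five highlight families (pathways, reactions, genes,
enzymes, compounds), each with exact and substring modes plus EC-number
and enzyme-name search for reactions and file input for genes. A search
yields a named overlay (colored primitives above the base tiles) and an
ordered found-object list with marker anchors. Gene matches expand to
the genes' products as drawn: reactions, RNAs, transporters, enzymes.

**Omics painting.** A tab-delimited table (rows = gene / protein /
reaction / compound labels, columns = experiments) is resolved onto map
elements; the global value range is mapped to a yellow→orange→red
spectrum shared by all columns, and each column becomes one overlay
frame of an animation. Base tiles are never touched.

## Worked example

```
$ cellmap demo --out demo_out --seed 0
{"frames": 3, "renders": 6, "stamp": "ca98eeb369565b41", "unresolved": 4}
```

This writes a synthetic demo organism (`network.yaml`), builds the full
map bundle (`demo_out/map`: 6 rendered levels — hence `renders: 6` — a
tile tree under `tiles/DEMO/<stamp>/`, and node/frame data under
`data/`), then paints a 40-row, 3-experiment omics sample onto zoom
level 2 (`frames: 3` overlay frames plus `legend.png`; 4 rows carry
deliberately unresolvable labels, reported as `unresolved: 4`).
Re-running `cellmap build-map demo_out/network.yaml --out demo_out/map`
prints `renders=0 cache_hits=6`: the network is unchanged, so the
stamp-keyed cache serves every level.

Searching highlights objects and lists them with their map anchors:

```
$ cellmap search demo_out/network.yaml --family genes --query arg
PROT-0001	argA enzyme	663,415
PROT-0021	argB enzyme	985,415
PROT-0041	argC enzyme	129,845
RXN-0001	remizeol => relovuate	645,415
RXN-0021	resanuine => zeminuol	967,415
RXN-0041	retonuine => fifilool	111,845
RXN-0061	safinuol => miguguol	160,244
PROT-0057	transporter argA permease	160,244
RNA-0001	tRNA-arg	46,1146
```

— a gene substring search finds reactions, RNAs, transporters and
enzymes, each with the master-coordinate anchor used for the "List"
marker.

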