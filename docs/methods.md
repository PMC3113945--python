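# Methods

## The diagram model

The toolkit draws a whole-organism metabolic map: every pathway,
reaction, metabolite, enzyme, transporter and tRNA of one organism on a
single canvas, structured by the cell's anatomy. The canvas is divided
into horizontal bands — extracellular space, outer membrane, periplasm,
inner membrane, cytoplasm — reflecting a Gram-negative two-membrane
template. A single-membrane organism is handled by degenerating the
periplasm to zero height (`LayoutConfig.single_membrane`).

Inside the cytoplasm, pathway placement encodes function: central
metabolism occupies the middle column and separates catabolism (right)
from anabolism and intermediary metabolism (left); signal-transduction
pathways sit in a strip along the bottom left; reactions not assigned
to any pathway form a rectangular grid at the far right. The
catabolic/anabolic classification cannot be derived reliably from
network structure alone, so pathway `category` is required input, never
guessed. Compartment beats category: a periplasmic or membrane reaction
is drawn in its band regardless of which pathway claims it, and a
reaction claimed by several pathways is drawn once, in the pathway with
the lexicographically smallest identifier (its other memberships still
drive search and overlays).

## Layout algorithm

No crossing-minimization or force direction is attempted; the layout is
a deterministic slot-packing scheme chosen so that the conventions
above hold *by construction* and the output is byte-identical across
runs:

* Each pathway is drawn as one or more vertical chain columns (at most
  8 steps per column): substrate row, blue reaction line, product row,
  repeating downward. Consecutive steps of a chain share the connecting
  metabolite glyph; every other occurrence of a metabolite gets its own
  local glyph. This yields strictly downward flow within chains and
  metabolite duplication across pathways, with no long connecting
  edges.
* Pathways are grouped by cluster label into shaded cluster boxes
  (pathways packed by descending reaction count, ties by frame id);
  cluster boxes are shelf-packed into a roughly square area per
  category; category areas are placed left-to-right in the fixed order
  anabolic/intermediary, central, catabolic, other, then the unassigned
  grid. A strict vertical stack of clusters per category would exceed
  the canvas bound for organism-scale networks, which is why areas are
  packed toward a square aspect instead.
* Transporters are boxes spanning their membrane band, evenly spaced;
  transport reactions are drawn through their transporter with the
  first substrate/product on either side of the band. Periplasmic
  reactions form a right-aligned row between the membranes; tRNAs (tee
  glyphs) line the bottom of the cytoplasm.

Coordinates are integers in *master units* (top-left origin, y
downward); one master unit is one pixel at the highest zoom level. The
canvas is bounded at 24,000×24,000 master units (organism-scale maps
reach beyond 20,000 pixels at top zoom); exceeding it is a hard error
reporting required vs. configured size.

## Semantic zoom and rendering

Six levels, scale factor 2 between adjacent levels (level k uses
2^(5−k) master units per pixel). The factor-2 ratio matches tile-map
convention and makes pixel positions at consecutive levels agree within
±1 px after half-up rounding, which is applied exactly once per level.

The feature policy is cumulative and configurable; the shipped default
is: level 0 — compound/transporter/RNA glyphs, reaction lines, cluster
shading; 1 — + pathway names; 2 — + enzyme glyphs; 3 — + compound
names; 4 — + enzyme and gene names; 5 — + EC numbers. Two points are
fixed by the diagram's convention: enzymes never appear at the lowest
level, and names only appear at higher magnification. The exact
level-to-class table beyond that is this package's own documented
default. Labels are placed greedily in deterministic order and dropped
(never truncated) on any collision with a glyph or earlier label —
consequently a small map at a low level may legitimately show no labels
at all.

Rasterization uses Pillow with its built-in bitmap font by default, so
identical inputs give identical pixel buffers; a TTF font may be
configured. The raster is format-independent; tiles are encoded as PNG
by default (GIF optional — PNG avoids palette-quantization
nondeterminism).

## Tiles and caching

400×200-pixel tiles; edge tiles are background-padded to full size so a
client can lay tiles contiguously. The cache path embeds the network's
content stamp (`root/organism/stamp/zoom/col_row.png`), a SHA-256 over
the canonicalized entity set — invariant under record reordering,
changed by any content edit. Invalidation is therefore atomic: a new
stamp directory is written and stale ones removed. On a miss the whole
level is rendered and sliced at once, amortizing rendering across that
level's tiles; a hit performs zero rendering (the pipeline exposes
render counters so this is testable).

## Search, node data, omics

The search index lowercases names, synonyms and frame ids once per
stamp. Matching convention: substring search is case-insensitive over
name/synonyms/frame id; exact search is case-sensitive on frame id (a
database key) and case-insensitive on name (human text), ignoring
synonyms. EC search matches whole numbers or dot-boundary prefixes.
Overlay primitives are stored in master coordinates and projected per
zoom at export time, so one search serves all levels. Hit-testing of
reaction lines uses a 3 px half-width corridor.

Omics values are mapped through an exact piecewise-linear ramp
(yellow→orange→red default, gray for missing) over the **global**
min/max of all selected columns — per-column scaling would make
animation frames incomparable, and the color key is shown once for the
whole animation. Out-of-range values clamp; a constant dataset maps to
the ramp midpoint; `log10` requires strictly positive values and errors
naming the offending row. Gene/protein rows paint their reaction steps;
an element receiving several rows takes their mean with a warning.
Interpolation is computed directly rather than through a lookup-table
colormap so ramp stops are hit exactly and output is deterministic.

## Synthetic organisms

The fixture generator emulates an organism-scale network: 2 central + 3
catabolic + 3 anabolic/intermediary + 1 signal pathway of 5 chain
reactions each, 12 unassigned reactions, 4 transporters (one in the
outer membrane), 3 periplasmic reactions, 3 tRNAs, one gene per enzyme,
a shared 4-compound cofactor pool (forcing metabolite duplication),
synonyms on half the entities and a 5% name-collision rate. These
defaults make every diagram region non-empty and every search mode
exercisable. Names are synthetic (syllable words with biochemical
suffixes, three-letter gene stems); no biological realism is claimed —
in particular the generator produces linear chains, so passing tests
say nothing about highly branched or cyclic pathway topologies, beyond
the branched-pathway allowance in the downward-flow check. All
randomness flows through one explicitly threaded seeded generator;
a spec reproduces a byte-identical network and stamp.

The oracle-scale fixture used for search testing (~5,000 entities, 206
pathways) runs index construction and exhaustive linear-scan
comparison in seconds; the demo organism (295 entities, canvas
1854×1180) keeps the full six-level render-and-slice pipeline under a
few seconds. These sizes were chosen to exercise organism-scale
behavior while keeping the whole suite fast.

## Numerical and degenerate-input choices

* Rounding: half-up (`floor(x+0.5)`) on both axes, once at layout
  specialization.
* Ties everywhere break on frame id; collections iterate sorted.
* Empty network → regions-only layout; empty zoom layout → uniform
  background raster of the computed size; empty overlay → empty found
  list, identity compositing.
* Duplicate omics labels: last wins, with a warning. Unresolvable
  labels and gene-file identifiers are reported, never fatal.

## Known limitations

* Layout is convention-faithful but not aesthetically optimized: no
  edge-crossing minimization, no curved pathway shapes (cycles render
  as chains), no hand-curated layouts.
* Signal-transduction pathways get region placement and generic chain
  drawing only, no pathway-internal signaling notation.
* Label fitting is greedy and order-based, not globally optimal.
* Raster determinism is guaranteed on a fixed platform/Pillow version,
  not across font rendering stacks if a custom TTF is configured.
* No HTTP server, no playback controls — frames and tiles are emitted
  as static files for an external client.
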