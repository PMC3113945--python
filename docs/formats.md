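# File formats

## Native network dialect (`cellmap-network/1`)

A YAML mapping with a `schema` tag, an `organism` identifier, and six
entity sections.  Every record has a unique `id` (the frame identifier, a
case-sensitive database key) and a non-empty `name`; `synonyms` is an
optional list.  All cross-references are by `id` and must resolve —
loading fails listing every dangling identifier.

```yaml
schema: cellmap-network/1
organism: DEMO
compounds:
  - {id: CPD-0001, name: glucose-like, synonyms: [GLC-x], formula: C6H12O6}
proteins:
  - {id: PROT-0001, name: argA enzyme, is_enzyme: true, is_transporter: false,
     genes: [G-0001]}
rnas:
  - {id: RNA-0001, name: tRNA-arg, genes: [G-0002]}
genes:
  - {id: G-0001, name: argA, products: [PROT-0001]}
reactions:
  - id: RXN-0001
    name: glucose-like => hexose-P-like
    substrates: [{compound: CPD-0001, coefficient: 1}]
    products: [{compound: CPD-0002, coefficient: 1}]
    ec_numbers: ["2.7.1.1"]
    enzymes: [PROT-0001]
    compartment: cytosol            # cytosol | periplasm | inner_membrane |
                                    # outer_membrane | extracellular
    pathways: [PWY-0001]            # empty => unassigned-reaction grid
pathways:
  - id: PWY-0001
    name: hexose degradation I
    reactions: [RXN-0001]           # ordered; at least one
    category: catabolic             # central | catabolic |
                                    # anabolic_intermediary | signal | other
    cluster: sugar degradation      # cluster-box grouping label
```

Stoichiometric coefficients must be positive.  `category` drives
horizontal placement and is required input — the toolkit does not guess
whether a pathway is catabolic.

## SBML import

SBML Level 2/3: species become compounds, reactions become reactions.
Compartment ids/names map onto the vocabulary above via a built-in table
(`c`/`cytosol`, `p`/`periplasm`, `e`/`extracellular`, `im`, `om`),
extendable per call; an unmapped compartment is an error unless a
default is supplied.  Pathway grouping comes from the SBML Groups
package or a sidecar file of tab-separated `reaction_id<TAB>pathway_id`
lines; ungrouped reactions go to the unassigned grid.

## Omics datafile

Tab-delimited text.  Column 1 is a row label (gene, protein, reaction or
compound identifier or name); remaining columns are experiments.  A
header row is auto-detected (first row whose value cells are all
non-numeric) and supplies experiment names.  `#` lines are comments;
non-numeric cells (`NA`, empty) are missing values; LF and CRLF both
work.  Duplicate labels keep the last occurrence.

## Published map bundle

```
<out>/<organism>.layout.json   master layout (master units)
<out>/tiles/<organism>/<stamp>/<zoom>/<col>_<row>.png   tile tree
<out>/data/nodedata_<zoom>.json   frame_id -> clickable primitives (px)
<out>/data/framedata.json         frame_id -> tooltip title/class/lines/links
```

Node-data primitives are `circle` (`cx`, `cy`, `r`), `rect`
(`x0,y0,x1,y1`) or `polyline` (`points`, hit-tested with a 3 px
half-width corridor).  Tiles are 400x200; edge tiles are padded with the
background color.  The `<stamp>` path component is the network content
hash: an unchanged network re-uses its tiles, a modified network gets a
fresh stamp directory.

## GET request contract

Highlight: `organism`, `zoom` (both required), `highlight` (family:
`pathways|reactions|genes|enzymes|compounds`), `mode`, `query`.
Omics: `organism`, `zoom`, `datafile` (`http://...` or `file://...`),
`columns` (comma-separated 0-based indices), `transform`
(`identity|log10`).  Unknown keys are rejected.
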