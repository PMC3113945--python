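"""Deterministic synthetic organisms for tests, demos and benchmarks.

``make_organism`` builds a PGDB-like network exercising every feature
class of the diagram: central pathways (glycolysis/TCA stand-ins) in the
middle, catabolic pathways on the right, anabolic/intermediary pathways
on the left, a signal-transduction pathway, a population of unassigned
reactions for the grid, periplasmic reactions, inner- and outer-membrane
transporters with transport reactions, tRNAs, enzymes, and genes.  Names
are synthetic (no biological realism is claimed) but follow the field's
surface conventions — three-letter gene stems, "X biosynthesis" pathway
names, EC numbers — so that search behavior is representative.

All randomness flows through one explicitly threaded ``numpy`` generator
seeded from the spec; the same spec yields a byte-identical network and
hence an identical version stamp.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
from pydantic import BaseModel, Field

from .network_model import (
    PGDB,
    Compartment,
    Compound,
    Gene,
    Participant,
    Pathway,
    PathwayCategory,
    Protein,
    Reaction,
    Rna,
    save_native,
)

_GENE_STEMS = [
    "arg", "lys", "met", "thr", "trp", "pur", "pyr", "gly", "ser", "his",
    "leu", "ile", "val", "cys", "asp", "glu", "pro", "tyr", "phe", "rib",
]

_PATHWAY_THEMES = {
    PathwayCategory.central: ["glycolysis-like core", "citrate-cycle-like core"],
    PathwayCategory.catabolic: [
        "hexose degradation", "amine degradation", "aromatic compound degradation",
        "fatty acid degradation", "purine salvage degradation",
    ],
    PathwayCategory.anabolic_intermediary: [
        "amino-acid biosynthesis", "cofactor biosynthesis", "nucleotide biosynthesis",
        "cell-wall precursor biosynthesis", "lipid biosynthesis",
    ],
    PathwayCategory.signal: ["two-component signalling"],
    PathwayCategory.other: ["miscellaneous conversions"],
}

_CLUSTER_OF_THEME = {
    "glycolysis-like core": "central metabolism",
    "citrate-cycle-like core": "central metabolism",
    "hexose degradation": "sugar degradation",
    "amine degradation": "nitrogen degradation",
    "aromatic compound degradation": "aromatic degradation",
    "fatty acid degradation": "lipid degradation",
    "purine salvage degradation": "nucleotide degradation",
    "amino-acid biosynthesis": "amino-acid biosynthesis",
    "cofactor biosynthesis": "cofactor biosynthesis",
    "nucleotide biosynthesis": "nucleotide biosynthesis",
    "cell-wall precursor biosynthesis": "cell-wall biosynthesis",
    "lipid biosynthesis": "lipid biosynthesis",
    "two-component signalling": "signal transduction",
    "miscellaneous conversions": "other pathways",
}

_EC_CLASSES = ["2.7.1", "1.1.1", "4.2.1", "2.6.1", "3.1.3", "6.3.2"]

_SYL = ["ba", "do", "fi", "gu", "ka", "lo", "mi", "nu", "pa", "re", "sa", "to", "vu", "ze"]


class FixtureSpec(BaseModel):
    """Counts and rates describing a synthetic organism."""

    seed: int = 0
    organism_id: str = "DEMO"
    pathways_per_category: dict[PathwayCategory, int] = Field(
        default_factory=lambda: {
            PathwayCategory.central: 2,
            PathwayCategory.catabolic: 3,
            PathwayCategory.anabolic_intermediary: 3,
            PathwayCategory.signal: 1,
        }
    )
    reactions_per_pathway: int = 5
    unassigned_reactions: int = 12
    transporters: int = 4
    periplasmic_reactions: int = 3
    rnas: int = 3
    genes_per_enzyme: int = 1
    synonym_density: float = 0.5
    name_collision_rate: float = 0.05


def _word(rng: np.random.Generator, n_syl: int = 3) -> str:
    return "".join(_SYL[rng.integers(0, len(_SYL))] for _ in range(n_syl))


class _Namer:
    def __init__(self, rng: np.random.Generator, spec: FixtureSpec):
        self.rng = rng
        self.spec = spec
        self.used: list[str] = []

    def compound(self) -> str:
        if self.used and self.rng.random() < self.spec.name_collision_rate:
            return self.used[int(self.rng.integers(0, len(self.used)))]
        name = _word(self.rng) + ["ate", "ose", "ine", "ol"][int(self.rng.integers(0, 4))]
        self.used.append(name)
        return name

    def synonyms(self, name: str) -> list[str]:
        if self.rng.random() < self.spec.synonym_density:
            return [name[:3].upper() + "-" + _word(self.rng, 2)]
        return []


def make_organism(spec: Optional[FixtureSpec] = None) -> PGDB:
    """Generate a validation-clean synthetic PGDB from the spec."""
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed)
    namer = _Namer(rng, spec)
    pgdb = PGDB(organism_id=spec.organism_id)
    counters = {"cpd": 0, "rxn": 0, "pwy": 0, "prot": 0, "gene": 0, "rna": 0}

    def next_id(kind: str, prefix: str) -> str:
        counters[kind] += 1
        return f"{prefix}-{counters[kind]:04d}"

    def new_compound() -> str:
        fid = next_id("cpd", "CPD")
        name = namer.compound()
        pgdb.compounds[fid] = Compound(
            frame_id=fid,
            name=name,
            synonyms=namer.synonyms(name),
            formula=f"C{int(rng.integers(1, 20))}H{int(rng.integers(1, 30))}O{int(rng.integers(0, 10))}",
        )
        return fid

    # shared cofactor pool: reused across pathways to force metabolite
    # duplication in the layout
    cofactors = [new_compound() for _ in range(4)]

    def new_enzyme(stem_i: int, transporter: bool = False) -> str:
        fid = next_id("prot", "PROT")
        stem = _GENE_STEMS[stem_i % len(_GENE_STEMS)]
        suffix = chr(ord("A") + (stem_i // len(_GENE_STEMS)) % 26)
        name = ("transporter " if transporter else "") + stem + suffix + (
            " permease" if transporter else " enzyme"
        )
        prot = Protein(
            frame_id=fid,
            name=name,
            synonyms=namer.synonyms(name),
            is_enzyme=not transporter,
            is_transporter=transporter,
            genes=[],
        )
        pgdb.proteins[fid] = prot
        for _ in range(spec.genes_per_enzyme):
            gid = next_id("gene", "G")
            gname = stem + suffix
            pgdb.genes[gid] = Gene(frame_id=gid, name=gname, products=[fid])
            prot.genes.append(gid)
        return fid

    stem_counter = 0

    def new_reaction(
        subs: list[str],
        prods: list[str],
        compartment: Compartment = Compartment.cytosol,
        pathway: Optional[str] = None,
        with_enzyme: bool = True,
        enzyme_id: Optional[str] = None,
    ) -> str:
        nonlocal stem_counter
        fid = next_id("rxn", "RXN")
        enzymes = []
        ecs = []
        if enzyme_id is not None:
            enzymes = [enzyme_id]
        elif with_enzyme:
            enzymes = [new_enzyme(stem_counter)]
            stem_counter += 1
        if with_enzyme:
            ec_class = _EC_CLASSES[counters["rxn"] % len(_EC_CLASSES)]
            ecs = [f"{ec_class}.{counters['rxn']}"]
        sub_names = pgdb.compounds[subs[0]].name if subs else "nothing"
        prod_names = pgdb.compounds[prods[0]].name if prods else "nothing"
        pgdb.reactions[fid] = Reaction(
            frame_id=fid,
            name=f"{sub_names} => {prod_names}",
            synonyms=[],
            substrates=[Participant(compound=c) for c in subs],
            products=[Participant(compound=c) for c in prods],
            ec_numbers=ecs,
            enzymes=enzymes,
            compartment=compartment,
            pathways=[pathway] if pathway else [],
        )
        return fid

    # --- pathways, one chain per pathway ------------------------------------
    for category, n_pwys in spec.pathways_per_category.items():
        themes = _PATHWAY_THEMES[category]
        for i in range(n_pwys):
            theme = themes[i % len(themes)]
            pwy_id = next_id("pwy", "PWY")
            roman = ["I", "II", "III", "IV", "V"][i // len(themes) % 5]
            pname = f"{_word(rng, 2)}{'ate' if i % 2 else 'ose'} {theme} {roman}"
            pwy = Pathway(
                frame_id=pwy_id,
                name=pname,
                synonyms=namer.synonyms(pname),
                reactions=[],
                category=category,
                cluster=_CLUSTER_OF_THEME[theme],
            )
            pgdb.pathways[pwy_id] = pwy
            chain = [new_compound() for _ in range(spec.reactions_per_pathway + 1)]
            for step in range(spec.reactions_per_pathway):
                subs = [chain[step]]
                prods = [chain[step + 1]]
                if rng.random() < 0.4:  # cofactor on the side
                    subs = subs + [cofactors[int(rng.integers(0, len(cofactors)))]]
                rid = new_reaction(subs, prods, pathway=pwy_id)
                pwy.reactions.append(rid)

    # --- unassigned grid -----------------------------------------------------
    for _ in range(spec.unassigned_reactions):
        subs = [new_compound()]
        prods = [new_compound()]
        new_reaction(subs, prods, with_enzyme=bool(rng.random() < 0.7))

    # --- periplasmic reactions ----------------------------------------------
    for _ in range(spec.periplasmic_reactions):
        new_reaction(
            [new_compound()], [new_compound()], compartment=Compartment.periplasm
        )

    # --- transporters with transport reactions -------------------------------
    for t in range(spec.transporters):
        compartment = (
            Compartment.outer_membrane if t % 4 == 3 else Compartment.inner_membrane
        )
        # transporter gene stems restart at the head of the stem list so the
        # common stems are represented across all product classes
        enz = new_enzyme(t, transporter=True)
        new_reaction(
            [new_compound()],
            [new_compound()],
            compartment=compartment,
            enzyme_id=enz,
        )

    # --- tRNAs ---------------------------------------------------------------
    for r in range(spec.rnas):
        rid = next_id("rna", "RNA")
        gid = next_id("gene", "G")
        stem = _GENE_STEMS[r % len(_GENE_STEMS)]
        rna = Rna(frame_id=rid, name=f"tRNA-{stem}", genes=[gid])
        pgdb.rnas[rid] = rna
        pgdb.genes[gid] = Gene(frame_id=gid, name=f"{stem}T", products=[rid])
    return pgdb


# ---------------------------------------------------------------------------
# Omics datafiles
# ---------------------------------------------------------------------------

def make_omics_file(
    pgdb: PGDB,
    path: Union[str, Path],
    n_rows: int = 50,
    n_cols: int = 3,
    seed: int = 0,
    miss_rate: float = 0.0,
    bad_label_rate: float = 0.0,
) -> dict:
    """Write a synthetic tab-delimited omics datafile.

    Row labels are drawn without replacement from the organism's genes,
    reactions, compounds and enzymes (all resolvable); exactly
    ``round(n_rows * bad_label_rate)`` rows get injected unresolvable
    labels.  Values are log-normal (mu=0, sigma=1); cells go missing
    ("NA") independently at ``miss_rate``.  Returns bookkeeping:
    ``{"labels", "bad_labels", "missing_cells", "experiment_names"}``.
    """
    if not 0 <= miss_rate <= 1 or not 0 <= bad_label_rate <= 1:
        raise ValueError("rates must be within [0, 1]")
    rng = np.random.default_rng(seed)
    enzyme_rxns = {e for r in pgdb.reactions.values() for e in r.enzymes}
    pool = (
        sorted(pgdb.reactions)
        + sorted(pgdb.compounds)
        + sorted(g for g, gene in pgdb.genes.items()
                 if any(p in enzyme_rxns for p in gene.products))
        + sorted(p for p in pgdb.proteins if p in enzyme_rxns)
    )
    n_bad = round(n_rows * bad_label_rate)
    n_good = n_rows - n_bad
    if n_good > len(pool):
        raise ValueError(f"not enough resolvable labels: need {n_good}, have {len(pool)}")
    good = [pool[i] for i in rng.choice(len(pool), size=n_good, replace=False)]
    bad = [f"BOGUS-{i:04d}" for i in range(n_bad)]
    labels = good + bad
    order = rng.permutation(len(labels))
    labels = [labels[i] for i in order]

    names = [f"exp{i + 1}" for i in range(n_cols)]
    missing_cells = 0
    lines = ["# synthetic omics datafile", "label\t" + "\t".join(names)]
    for label in labels:
        cells = []
        for _ in range(n_cols):
            if rng.random() < miss_rate:
                cells.append("NA")
                missing_cells += 1
            else:
                cells.append(f"{float(rng.lognormal(0.0, 1.0)):.4f}")
        lines.append(label + "\t" + "\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")
    return {
        "labels": labels,
        "bad_labels": sorted(bad),
        "missing_cells": missing_cells,
        "experiment_names": names,
    }


# ---------------------------------------------------------------------------
# Demo bundle
# ---------------------------------------------------------------------------

def write_demo_bundle(outdir: Union[str, Path], seed: int = 0) -> dict:
    """Write the demo organism bundle: native network file, omics sample,
    and a digest file pinning the expected outputs."""
    from .layout_engine import layout_master

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = FixtureSpec(seed=seed)
    pgdb = make_organism(spec)
    network = outdir / "network.yaml"
    save_native(pgdb, network)
    omics = outdir / "omics.tsv"
    make_omics_file(pgdb, omics, n_rows=40, n_cols=3, seed=seed, miss_rate=0.1, bad_label_rate=0.1)
    master = layout_master(pgdb)
    digests = {
        "version_stamp": pgdb.version_stamp,
        "master_layout_sha256": hashlib.sha256(master.to_json().encode()).hexdigest(),
        "network_sha256": hashlib.sha256(network.read_bytes()).hexdigest(),
        "omics_sha256": hashlib.sha256(omics.read_bytes()).hexdigest(),
    }
    (outdir / "digests.json").write_text(json.dumps(digests, indent=2, sort_keys=True))
    return digests
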