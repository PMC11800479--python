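"""Truth-labeled synthetic datasets emulating an HGT-detection study.

The generator builds, for two closely related recipient (insect) species
plus an optional cryptic sister species, everything the pipeline consumes:
a small NCBI-style taxonomy with an animal recipient clade and three donor
kingdoms (Bacteria, Fungi, Viridiplantae); per-species tabular homology
hits whose bitscores decay linearly with latent evolutionary distance
(``bitscore = aln_length * (a - b*d) + N(0, sd)``, truncated positive) and
whose identities decay likewise; planted transfer genes whose best
non-self hits lie in their donor kingdom; database contaminants copied
near-verbatim from donor sequences (no cryptic-species homolog, > 70%
identity top hits); multi-gene scaffolds; cross-species orthogroups;
domain and GO annotations with one GO term enriched among transfers; and
per-family amino-acid alignments simulated on explicit generating trees.

Hit tables are generated directly from the latent distances rather than by
running an aligner: the pipeline consumes tabular hits, so fidelity at the
hit-table level is the simulation boundary. Sequence-level realism
(indels, domain shuffling, rate heterogeneity) is deliberately absent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .phylo import AA, Alignment, write_fasta_alignment
from .trees import Node, Tree, write_newick

__all__ = ["ScenarioConfig", "SyntheticDataset", "generate_scenario",
           "simulate_alignment", "truth_evaluation"]

# fixed synthetic taxids
ROOT, ANIMALS, BACTERIA, FUNGI, PLANTS = 1, 2, 3, 4, 5
SELF_CLADE, SPECIES_A, SPECIES_B, CRYPTIC = 20, 21, 22, 23
KINGDOM_TAXID = {"bacteria": BACTERIA, "fungi": FUNGI, "viridiplantae": PLANTS}
KINGDOM_BASE = {"animal": 100, "bacteria": 200, "fungi": 300, "viridiplantae": 400}


def _default_planted() -> dict[str, int]:
    return {"bacteria": 8, "fungi": 6, "viridiplantae": 6}


def _default_taxa() -> dict[str, int]:
    return {"animal": 13, "bacteria": 9, "fungi": 9, "viridiplantae": 9}


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic dataset.

    Defaults are sized so the full pipeline runs end to end on a single
    core in minutes: two recipient species with 300 genes each, 40 database
    taxa, 20 planted transfer families across the three donor kingdoms
    (half predating the species split), and 2 injected contaminants.
    """

    seed: int = 1
    n_database_taxa: dict[str, int] = field(default_factory=_default_taxa)
    species: tuple[str, str] = ("spA", "spB")
    cryptic_species: bool = True
    n_genes: int = 300  # per species
    n_planted_hgt: dict[str, int] = field(default_factory=_default_planted)
    fraction_shared: float = 0.5  # single pre-divergence acquisition, both species
    fraction_independent: float = 0.0  # two convergent acquisitions, both species
    contamination_injections: int = 2
    # bitscore model: bitscore = L * (slope_a - slope_b * distance) + N(0, noise_sd)
    slope_a: float = 1.5
    slope_b: float = 0.5
    noise_sd: float = 5.0
    n_scaffolds: int = 15
    n_sites: int = 300  # columns per simulated family alignment
    # GO model
    go_n_leaf_terms: int = 24
    go_annotation_rate: float = 0.7
    go_enriched_effect: float = 0.7  # P(term | transfer gene); background 0.03


@dataclass
class PlantedEvent:
    event_id: str
    kingdom: str
    sharing: str  # ancestral | independent | single
    species: tuple[str, ...]
    genes: dict[str, str]  # species -> gene id
    donor_taxids: list[int]
    base_distance: float


@dataclass
class SyntheticDataset:
    config: ScenarioConfig
    taxonomy_rows: list[tuple[int, int, str, str]]
    hits: dict[str, pd.DataFrame]  # species -> canonical hit-table frame
    gene_maps: dict[str, dict[str, list[str]]]  # species -> scaffold -> genes
    orthogroups: dict[str, str]
    domains: dict[str, set[str]]
    go_parents: dict[str, set[str]]
    go_annotations: dict[str, set[str]]
    cryptic_homologs: dict[str, bool]
    alignments: dict[str, Alignment]  # family id -> alignment
    gen_trees: dict[str, Tree]
    seq_index: dict[str, str]  # sequence/gene id -> family id
    proteomes: dict[str, dict[str, str]]  # species -> gene -> sequence
    truth: dict

    def write(self, out_dir: str | Path) -> Path:
        """Emit every file dialect the pipeline readers consume."""
        out = Path(out_dir)
        (out / "alignments").mkdir(parents=True, exist_ok=True)
        (out / "gen_trees").mkdir(exist_ok=True)
        with open(out / "taxonomy.tsv", "w") as fh:
            for row in self.taxonomy_rows:
                fh.write("\t".join(map(str, row)) + "\n")
        for sp, df in self.hits.items():
            emit = df.copy()
            emit["staxids"] = emit["subject_taxids"].map(lambda ts: ";".join(map(str, ts)))
            emit = emit.rename(columns={
                "query_id": "qseqid", "subject_id": "sseqid",
                "pct_identity": "pident", "aln_length": "length",
                "query_coverage": "qcovhsp"})
            emit[["qseqid", "sseqid", "pident", "length", "evalue", "bitscore",
                  "staxids", "qcovhsp"]].to_csv(out / f"hits_{sp}.tsv", sep="\t", index=False)
        for sp, scaffolds in self.gene_maps.items():
            with open(out / f"genemap_{sp}.tsv", "w") as fh:
                for scaf, genes in scaffolds.items():
                    for i, g in enumerate(genes):
                        fh.write(f"{g}\t{scaf}\t{i * 1000 + 1}\t{i * 1000 + 900}\n")
        with open(out / "orthogroups.tsv", "w") as fh:
            for g, og in sorted(self.orthogroups.items()):
                fh.write(f"{g}\t{og}\n")
        with open(out / "domains.tsv", "w") as fh:
            for g, doms in sorted(self.domains.items()):
                for d in sorted(doms):
                    fh.write(f"{g}\t{d}\n")
        with open(out / "go_dag.tsv", "w") as fh:
            for t, parents in sorted(self.go_parents.items()):
                if parents:
                    for p in sorted(parents):
                        fh.write(f"{t}\t{p}\n")
                else:
                    fh.write(f"{t}\t-\n")
        with open(out / "go_annotations.tsv", "w") as fh:
            for g, terms in sorted(self.go_annotations.items()):
                for t in sorted(terms):
                    fh.write(f"{g}\t{t}\n")
        with open(out / "cryptic_homologs.tsv", "w") as fh:
            for g, present in sorted(self.cryptic_homologs.items()):
                fh.write(f"{g}\t{int(present)}\n")
        with open(out / "seq_index.tsv", "w") as fh:
            for sid, fam in sorted(self.seq_index.items()):
                fh.write(f"{sid}\t{fam}\n")
        for fam, aln in self.alignments.items():
            write_fasta_alignment(aln, out / "alignments" / f"{fam}.fasta")
        for fam, tree in self.gen_trees.items():
            (out / "gen_trees" / f"{fam}.nwk").write_text(write_newick(tree) + "\n")
        for sp, prot in self.proteomes.items():
            with open(out / f"proteome_{sp}.fasta", "w") as fh:
                for g, seq in sorted(prot.items()):
                    fh.write(f">{g}\n{seq}\n")
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)
        with open(out / "scenario.json", "w") as fh:
            json.dump(asdict(self.config), fh, indent=1, sort_keys=True)
        return out


# --------------------------------------------------------------------------
# sequence simulation
def simulate_alignment(tree: Tree, n_sites: int, seed: int) -> Alignment:
    """Evolve i.i.d. sites under the 20-state Poisson model from a uniform
    root; deterministic given the seed."""
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    k = 20
    seqs: dict[int, np.ndarray] = {}
    root_seq = rng.integers(0, k, size=n_sites)
    seqs[id(tree.root)] = root_seq
    ids, rows = [], []
    for node in tree.preorder():
        if node is tree.root:
            continue
        parent_seq = seqs[id(node.parent)]
        stay = rng.random(n_sites) < np.exp(-k * max(node.length, 0.0) / (k - 1))
        redraw = rng.integers(0, k, size=n_sites)
        seqs[id(node)] = np.where(stay, parent_seq, redraw)
        if node.is_leaf:
            ids.append(node.name)
            rows.append("".join(AA[c] for c in seqs[id(node)]))
    order = np.argsort(ids, kind="stable")
    return Alignment([ids[i] for i in order], [rows[i] for i in order])


# --------------------------------------------------------------------------
# family tree construction
def _caterpillar(leaves: list[tuple[str, float]], internal: float) -> Node:
    """((l1,l2),l3),... with given terminal lengths and internal branch."""
    name, ln = leaves[0]
    node = Node(name, ln)
    for name, ln in leaves[1:]:
        parent = Node(None, internal)
        parent.add(node)
        parent.add(Node(name, ln))
        node = parent
    return node


def _family_tree(
    queries: dict[str, str],
    donor_ids: list[str],
    animal_ids: list[str],
    sharing: str,
    cryptic_id: str | None,
    rng: np.random.Generator,
    contaminant: bool = False,
) -> Tree:
    """Generating tree: queries grafted inside a donor-kingdom clade, with a
    distant animal outgroup clade on a long stem (so midpoint rooting
    separates animals from the donor side)."""
    td = lambda: float(rng.uniform(0.08, 0.13))  # noqa: E731 donor terminal
    ti = 0.08  # donor internal
    tq = 0.02 if contaminant else 0.08  # query terminal
    qs = sorted(queries.values())

    def query_node(gene: str) -> Node:
        return Node(gene, tq)

    if sharing == "ancestral" and len(qs) == 2:
        q = Node(None, 0.10)
        q.add(query_node(qs[0]))
        q.add(query_node(qs[1]))
        if cryptic_id:
            outer = Node(None, 0.06)
            outer.add(q)
            outer.add(Node(cryptic_id, 0.09))
            q = outer
    else:
        q = query_node(qs[0])
        if cryptic_id:
            outer = Node(None, 0.06)
            outer.add(q)
            outer.add(Node(cryptic_id, 0.05))
            q = outer

    def pair(a: str, b: str) -> Node:
        p = Node(None, ti)
        p.add(Node(a, td()))
        p.add(Node(b, td()))
        return p

    d = list(donor_ids)
    if sharing == "independent" and len(qs) == 2:
        # two separate grafts divided by donor clades
        left = Node(None, ti)
        left.add(q if not cryptic_id else q)  # species-A query (+cryptic)
        left.add(pair(d[0], d[1]))
        left2 = Node(None, ti)
        left2.add(left)
        left2.add(pair(d[2], d[3]))
        right = Node(None, ti)
        right.add(query_node(qs[1]))
        right.add(pair(d[4], d[5]))
        core = Node(None, ti)
        core.add(left2)
        core.add(right)
        rest = d[6:]
    else:
        inner = Node(None, ti)
        inner.add(q)
        inner.add(pair(d[0], d[1]))
        core = Node(None, ti)
        core.add(inner)
        core.add(pair(d[2], d[3]))
        rest = d[4:]
    # chain the remaining donors as paired outgroups to keep the donor side
    # shallow (midpoint rooting must land on the animal stem)
    for a, b in zip(rest[0::2], rest[1::2]):
        parent = Node(None, ti)
        parent.add(core)
        parent.add(pair(a, b))
        core = parent
    if len(rest) % 2:
        parent = Node(None, ti)
        parent.add(core)
        parent.add(Node(rest[-1], td()))
        core = parent
    core.length = 0.15

    animal = _caterpillar([(a, 0.10) for a in animal_ids], 0.08)
    animal.length = 0.50
    root = Node(None, 0.0)
    root.add(core)
    root.add(animal)
    return Tree(root, rooted=True)


# --------------------------------------------------------------------------
def _identity(dist: float, rng: np.random.Generator) -> float:
    return float(np.clip(88.0 - 30.0 * dist + rng.normal(0, 2.0), 8.0, 98.0))


def generate_scenario(config: ScenarioConfig) -> SyntheticDataset:
    """Build a complete dataset (see module docstring); deterministic per seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    sp_a, sp_b = cfg.species
    species_taxid = {sp_a: SPECIES_A, sp_b: SPECIES_B}

    n_events = sum(cfg.n_planted_hgt.values())
    if n_events + cfg.contamination_injections > cfg.n_genes:
        raise ValueError("more planted genes than genes per species")

    # --- taxonomy -----------------------------------------------------------
    tax_rows: list[tuple[int, int, str, str]] = [
        (ROOT, ROOT, "no rank", "root"),
        (ANIMALS, ROOT, "kingdom", "Animals"),
        (BACTERIA, ROOT, "superkingdom", "Bacteria"),
        (FUNGI, ROOT, "kingdom", "Fungi"),
        (PLANTS, ROOT, "kingdom", "Viridiplantae"),
        (SELF_CLADE, ANIMALS, "subfamily", "RecipientSubfamily"),
        (SPECIES_A, SELF_CLADE, "species", sp_a),
        (SPECIES_B, SELF_CLADE, "species", sp_b),
    ]
    if cfg.cryptic_species:
        tax_rows.append((CRYPTIC, SELF_CLADE, "species", "cryptic"))
    db_taxa: dict[str, list[int]] = {}
    taxon_dist: dict[int, float] = {}
    for kingdom, n in cfg.n_database_taxa.items():
        parent = ANIMALS if kingdom == "animal" else KINGDOM_TAXID[kingdom]
        base = KINGDOM_BASE[kingdom]
        db_taxa[kingdom] = []
        for i in range(n):
            taxid = base + i
            tax_rows.append((taxid, parent, "species", f"{kingdom}_{i}"))
            db_taxa[kingdom].append(taxid)
            if kingdom == "animal":
                taxon_dist[taxid] = float(rng.uniform(0.25, 0.9))
            else:
                taxon_dist[taxid] = float(rng.uniform(1.3, 2.0))

    # --- planted events -----------------------------------------------------
    kingdoms = [k for k, n in sorted(cfg.n_planted_hgt.items()) for _ in range(n)]
    rng.shuffle(kingdoms)
    n_shared = int(round(cfg.fraction_shared * n_events))
    n_indep = int(round(cfg.fraction_independent * n_events))
    sharings = (["ancestral"] * n_shared + ["independent"] * n_indep
                + ["single"] * (n_events - n_shared - n_indep))
    gene_ids = {sp: [f"{sp}_g{i:04d}" for i in range(cfg.n_genes)] for sp in cfg.species}
    pick = {sp: list(rng.permutation(cfg.n_genes)) for sp in cfg.species}

    events: list[PlantedEvent] = []
    for e, (kingdom, sharing) in enumerate(zip(kingdoms, sharings)):
        eid = f"E{e:03d}"
        if sharing == "single":
            sps: tuple[str, ...] = (cfg.species[e % 2],)
        else:
            sps = cfg.species
        genes = {sp: gene_ids[sp][pick[sp].pop()] for sp in sps}
        donor_pool = db_taxa[kingdom]
        n_donor = min(8, len(donor_pool))
        donors = sorted(rng.choice(donor_pool, size=n_donor, replace=False).tolist())
        events.append(PlantedEvent(eid, kingdom, sharing, sps, genes, donors,
                                   float(rng.uniform(0.9, 1.3))))

    contaminants: list[tuple[str, str, str, list[int]]] = []  # (gene, species, kingdom, donors)
    donor_kingdom_names = sorted(cfg.n_planted_hgt)
    for c in range(cfg.contamination_injections):
        kingdom = donor_kingdom_names[c % len(donor_kingdom_names)]
        gene = gene_ids[sp_a][pick[sp_a].pop()]
        pool = db_taxa[kingdom]
        donors = sorted(rng.choice(pool, size=min(8, len(pool)), replace=False).tolist())
        contaminants.append((gene, sp_a, kingdom, donors))

    gene_role: dict[str, tuple[str, object]] = {}  # gene -> ("hgt", event) | ("contaminant", rec)
    for ev in events:
        for sp, g in ev.genes.items():
            gene_role[g] = ("hgt", ev)
    for rec in contaminants:
        gene_role[rec[0]] = ("contaminant", rec)

    # --- hit tables, families, alignments ----------------------------------
    hit_rows: dict[str, list[dict]] = {sp: [] for sp in cfg.species}
    seq_index: dict[str, str] = {}
    alignments: dict[str, Alignment] = {}
    gen_trees: dict[str, Tree] = {}
    cryptic_homologs: dict[str, bool] = {}

    def add_hit(sp, query, subject, taxids, dist, L, qcov_mu=85.0):
        bits = max(float(L * (cfg.slope_a - cfg.slope_b * dist) + rng.normal(0, cfg.noise_sd)),
                   25.0)
        hit_rows[sp].append({
            "query_id": query,
            "subject_id": subject,
            "pct_identity": round(_identity(dist, rng), 1),
            "aln_length": int(L),
            "evalue": float(f"{10 ** (-bits / 10):.3g}") if bits < 120 else 0.0,
            "bitscore": round(bits, 1),
            "subject_taxids": list(taxids),
            "query_coverage": round(float(np.clip(rng.normal(qcov_mu, 8), 30, 100)), 1),
        })

    def build_family(fam: str, queries: dict[str, str], donors: list[int],
                     kingdom: str, sharing: str, base_dist: float,
                     contaminant: bool = False) -> None:
        """Emit hits, alignment and generating tree for one transfer family."""
        L = int(rng.integers(180, 320))
        animal_ctx = sorted(rng.choice(db_taxa["animal"], size=3, replace=False).tolist())
        donor_ids = [f"P{t}_{fam}" for t in donors]
        animal_ids = [f"P{t}_{fam}" for t in animal_ctx]
        cryptic_id = f"C{CRYPTIC}_{fam}" if (cfg.cryptic_species and not contaminant) else None
        for sp, g in queries.items():
            seq_index[g] = fam
            for t, did in zip(donors, donor_ids):
                d = base_dist + float(rng.uniform(0, 0.25))
                if contaminant:
                    d = float(rng.uniform(0.02, 0.12))
                add_hit(sp, g, did, [t], d, L)
            for t, aid in zip(animal_ctx, animal_ids):
                add_hit(sp, g, aid, [t], float(rng.uniform(1.8, 2.4)), L)
            if cryptic_id:
                add_hit(sp, g, cryptic_id, [CRYPTIC], 0.15, L)
            cryptic_homologs[g] = not contaminant
        for sid in donor_ids + animal_ids + ([cryptic_id] if cryptic_id else []):
            seq_index[sid] = fam
        tree = _family_tree(queries, donor_ids, animal_ids, sharing, cryptic_id,
                            rng, contaminant)
        gen_trees[fam] = tree
        alignments[fam] = simulate_alignment(
            tree, cfg.n_sites, int(rng.integers(0, 2**31 - 1)))

    for ev in events:
        build_family(ev.event_id, ev.genes, ev.donor_taxids, ev.kingdom,
                     ev.sharing, ev.base_distance)
    for ci, (gene, sp, kingdom, donors) in enumerate(contaminants):
        fam = f"CONTAM{ci:02d}"
        build_family(fam, {sp: gene}, donors, kingdom, "single", 0.05,
                     contaminant=True)

    # vertical genes: animal-dominated hit profiles (paired across species)
    for i in range(cfg.n_genes):
        ga, gb = gene_ids[sp_a][i], gene_ids[sp_b][i]
        if ga in gene_role and gb in gene_role:
            continue
        L = int(rng.integers(150, 350))
        m = int(rng.integers(8, min(14, len(db_taxa["animal"])) + 1))
        chosen = sorted(rng.choice(db_taxa["animal"], size=m, replace=False).tolist())
        fam = f"VF{i:04d}"
        for sp, g in ((sp_a, ga), (sp_b, gb)):
            if g in gene_role:
                continue
            for t in chosen:
                add_hit(sp, g, f"P{t}_{fam}", [t], taxon_dist[t] + float(rng.uniform(0, 0.3)), L)
            if rng.random() < 0.3:
                kingdom = donor_kingdom_names[int(rng.integers(len(donor_kingdom_names)))]
                t = int(rng.choice(db_taxa[kingdom]))
                add_hit(sp, g, f"P{t}_{fam}", [t], float(rng.uniform(1.6, 2.2)), L)
            if rng.random() < 0.2:  # junk hit above the e-value threshold
                t = int(rng.choice(db_taxa["animal"]))
                hit_rows[sp].append({
                    "query_id": g, "subject_id": f"P{t}_{fam}_junk",
                    "pct_identity": 22.0, "aln_length": 40, "evalue": 1e-2,
                    "bitscore": 28.0, "subject_taxids": [t], "query_coverage": 12.0,
                })
            cryptic_homologs.setdefault(g, True)

    hits = {sp: pd.DataFrame.from_records(rows) for sp, rows in hit_rows.items()}

    # --- proteomes ----------------------------------------------------------
    proteomes: dict[str, dict[str, str]] = {sp: {} for sp in cfg.species}
    for sp in cfg.species:
        for g in gene_ids[sp]:
            fam = seq_index.get(g)
            if fam is not None:
                proteomes[sp][g] = alignments[fam].row(g).replace("-", "")
            else:
                n = int(rng.integers(120, 400))
                proteomes[sp][g] = "".join(AA[c] for c in rng.integers(0, 20, size=n))

    # --- gene maps ----------------------------------------------------------
    gene_maps: dict[str, dict[str, list[str]]] = {}
    for sp in cfg.species:
        order = [gene_ids[sp][i] for i in rng.permutation(cfg.n_genes)]
        per = int(np.ceil(cfg.n_genes / cfg.n_scaffolds))
        scaffolds = {}
        for j in range(cfg.n_scaffolds):
            chunk = order[j * per : (j + 1) * per]
            if chunk:
                scaffolds[f"{sp}_scaf{j:02d}"] = chunk
        gene_maps[sp] = scaffolds

    # --- orthogroups and domains -------------------------------------------
    orthogroups: dict[str, str] = {}
    domains: dict[str, set[str]] = {}
    for i in range(cfg.n_genes):
        ga, gb = gene_ids[sp_a][i], gene_ids[sp_b][i]
        if ga not in gene_role and gb not in gene_role:
            orthogroups[ga] = orthogroups[gb] = f"OG{i:05d}"
            dom = f"PF{10000 + i % 200}"
            domains.setdefault(ga, set()).add(dom)
            domains.setdefault(gb, set()).add(dom)
    for e, ev in enumerate(events):
        for g in ev.genes.values():
            orthogroups[g] = f"OGE{e:03d}"
            domains.setdefault(g, set()).add(f"PF9{e:04d}")
    # contaminants: no orthogroup (absent from the related species), own domain
    for ci, (gene, *_rest) in enumerate(contaminants):
        domains.setdefault(gene, set()).add(f"PF8{ci:04d}")

    # --- GO -----------------------------------------------------------------
    go_parents: dict[str, set[str]] = {"GO:0000000": set()}
    mids = [f"GO:000000{i}" for i in range(1, 5)]
    for m in mids:
        go_parents[m] = {"GO:0000000"}
    leaves = [f"GO:00001{i:02d}" for i in range(cfg.go_n_leaf_terms)]
    for i, t in enumerate(leaves):
        go_parents[t] = {mids[i % len(mids)]}
    enriched_term = leaves[0]
    go_annotations: dict[str, set[str]] = {}
    for sp in cfg.species:
        for g in gene_ids[sp]:
            terms: set[str] = set()
            if rng.random() < cfg.go_annotation_rate:
                n = int(rng.integers(1, 3))
                terms |= set(rng.choice(leaves[1:], size=n, replace=False).tolist())
            role = gene_role.get(g, ("vertical",))[0]
            p_enriched = cfg.go_enriched_effect if role == "hgt" else 0.03
            if rng.random() < p_enriched:
                terms.add(enriched_term)
            if terms:
                go_annotations[g] = terms

    # --- truth --------------------------------------------------------------
    truth_genes: dict[str, dict] = {}
    for sp in cfg.species:
        for g in gene_ids[sp]:
            role = gene_role.get(g)
            if role is None:
                truth_genes[g] = {"label": "vertical"}
            elif role[0] == "hgt":
                ev = role[1]
                truth_genes[g] = {"label": "hgt", "kingdom": ev.kingdom,
                                  "event": ev.event_id}
            else:
                truth_genes[g] = {"label": "contaminant", "kingdom": role[1][2]}
    truth_events = {
        ev.event_id: {
            "kingdom": ev.kingdom,
            "sharing": ev.sharing,
            "n_acquisitions": 2 if ev.sharing == "independent" else 1,
            "genes": sorted(ev.genes.values()),
        }
        for ev in events
    }
    truth = {
        "genes": truth_genes,
        "events": truth_events,
        "enriched_go_term": enriched_term,
        "contaminants": sorted(rec[0] for rec in contaminants),
    }

    return SyntheticDataset(
        config=cfg,
        taxonomy_rows=tax_rows,
        hits=hits,
        gene_maps=gene_maps,
        orthogroups=orthogroups,
        domains=domains,
        go_parents=go_parents,
        go_annotations=go_annotations,
        cryptic_homologs=cryptic_homologs,
        alignments=alignments,
        gen_trees=gen_trees,
        seq_index=seq_index,
        proteomes=proteomes,
        truth=truth,
    )


# --------------------------------------------------------------------------
def truth_evaluation(result, truth: dict) -> dict[str, float]:
    """Score pipeline output against the generator's truth labels.

    ``result`` needs: ``validated_genes`` (set), ``rejected_genes`` (set),
    ``origin_by_gene`` (gene -> origin label), ``n_events`` (int, total
    inferred acquisitions over validated groups) and ``sharing_by_genes``
    (frozenset of genes -> verdict). Returns sensitivity, false-positive
    rate, donor-origin accuracy, event-count error, sharing accuracy and
    contaminant rejection rate.
    """
    genes = truth["genes"]
    planted = {g for g, t in genes.items() if t["label"] == "hgt"}
    vertical = {g for g, t in genes.items() if t["label"] == "vertical"}
    contams = set(truth["contaminants"])
    universe = set(genes)
    called = set(result.validated_genes) | set(result.rejected_genes)
    unknown = called - universe
    if unknown:
        raise ValueError(f"called genes not in truth: {sorted(unknown)[:5]}")

    validated = set(result.validated_genes)
    sensitivity = len(validated & planted) / len(planted) if planted else float("nan")
    fpr = len(validated & vertical) / len(vertical) if vertical else 0.0
    tp = validated & planted
    correct_origin = sum(
        1 for g in tp if result.origin_by_gene.get(g) == genes[g]["kingdom"]
    )
    origin_accuracy = correct_origin / len(tp) if tp else float("nan")
    contaminant_rejection = (
        len(contams - validated) / len(contams) if contams else float("nan")
    )

    true_acq = sum(
        ev["n_acquisitions"]
        for ev in truth["events"].values()
        if set(ev["genes"]) & validated
    )
    event_count_error = abs(result.n_events - true_acq)

    # sharing: evaluated per planted two-species family with both genes validated
    n_sharing = n_sharing_ok = 0
    for ev in truth["events"].values():
        if ev["sharing"] not in ("ancestral", "independent"):
            continue
        ev_genes = set(ev["genes"])
        if not ev_genes <= validated:
            continue
        verdict = None
        for members, v in result.sharing_by_genes.items():
            if ev_genes <= set(members):
                verdict = v
                break
        n_sharing += 1
        want = "single_ancestral" if ev["sharing"] == "ancestral" else "independent"
        if verdict == want:
            n_sharing_ok += 1
    sharing_accuracy = n_sharing_ok / n_sharing if n_sharing else float("nan")

    return {
        "sensitivity": sensitivity,
        "false_positive_rate": fpr,
        "origin_accuracy": origin_accuracy,
        "event_count_error": float(event_count_error),
        "sharing_accuracy": sharing_accuracy,
        "contaminant_rejection_rate": contaminant_rejection,
    }
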