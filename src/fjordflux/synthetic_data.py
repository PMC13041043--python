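"""Synthetic study generator with known ground truth.

Produces the inputs every other module consumes: two-endmember
salinity/nutrient transects with an optional imposed upper-100 m
biogeochemical sink, vertically layered water columns covering all seven
envelope classes, Dirichlet-multinomial taxa tables whose composition
depends on water mass and depth (with a depth-increasing nitrifier
fraction), and Poisson gene-count tables with known per-genome copy
numbers.  All generators are seed-deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .watermass import compute_sigma_theta

__all__ = [
    "DEFAULT_LAYERS",
    "TransectConfig",
    "CommunityConfig",
    "GeneSimConfig",
    "generate_profiles",
    "generate_taxa_table",
    "generate_gene_counts",
    "generate_full_study",
]

# depth (m), temperature, fjord/shelf salinities, intended water-mass label.
# Salinities sit inside the default envelope windows with margin for the
# per-station offsets below.
DEFAULT_LAYERS = (
    {"depth": 5.0, "temp": 4.0, "s_fjord": 33.00, "s_shelf": 33.50, "label": "SW"},
    {"depth": 20.0, "temp": 3.0, "s_fjord": 34.20, "s_shelf": 34.40, "label": "IW"},
    {"depth": 50.0, "temp": 4.0, "s_fjord": 34.95, "s_shelf": 35.05, "label": "AW"},
    {"depth": 80.0, "temp": 2.0, "s_fjord": 34.75, "s_shelf": 34.85, "label": "TAW"},
    {"depth": 150.0, "temp": 0.0, "s_fjord": 34.50, "s_shelf": 34.60, "label": "ArW"},
    {"depth": 250.0, "temp": 0.5, "s_fjord": 34.82, "s_shelf": 34.84, "label": "LW"},
    {"depth": 400.0, "temp": -1.0, "s_fjord": 34.90, "s_shelf": 34.95, "label": "WCW"},
)

DEFAULT_MARINE_CONC = {
    "ammonium": 8.0,
    "nitrate_nitrite": 12.0,
    "nitrite": 8.0,
    "phosphate": 9.0,
    "silicic_acid": 10.0,
}


@dataclass
class TransectConfig:
    """One region-year transect of shelf and fjord stations."""

    region: str = "fjordA"
    year: int = 2016
    n_fjord: int = 4
    n_shelf: int = 3
    s_marine: float = 35.2
    marine_conc: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MARINE_CONC))
    s_fresh: float = 0.0
    fresh_conc: dict[str, float] = field(default_factory=dict)  # default 0
    layers: tuple[dict, ...] = DEFAULT_LAYERS
    sink_delta: float = 0.0          # umol kg^-1 removed in fjord top 100 m
    depth_cutoff: float = 100.0
    noise_sd: float = 0.0
    station_spread: float = 0.008    # max per-station salinity offset
    seed: int = 0

    def __post_init__(self):
        if self.sink_delta < 0:
            raise ValueError("sink_delta must be >= 0")

    @property
    def fjord_stations(self) -> list[str]:
        return [f"{self.region}-F{i}" for i in range(1, self.n_fjord + 1)]

    @property
    def shelf_stations(self) -> list[str]:
        return [f"{self.region}-X{i}" for i in range(1, self.n_shelf + 1)]


def _mixing_line(cfg: TransectConfig, analyte: str):
    """Concentration as a function of salinity on the conservative line."""
    c_m = cfg.marine_conc[analyte]
    c_f = cfg.fresh_conc.get(analyte, 0.0)
    slope = (c_m - c_f) / (cfg.s_marine - cfg.s_fresh)

    def line(s):
        return c_f + (s - cfg.s_fresh) * slope

    return line


def generate_profiles(cfg: TransectConfig
                      ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """CTD table, nutrient table and a truth record for one transect.

    Every sample lies exactly on the two-endmember mixing line for each
    analyte; fjord-side samples shallower than the cutoff are reduced by
    ``sink_delta``; optional Gaussian noise (truncated at zero) is added
    afterwards.
    """
    rng = np.random.default_rng(cfg.seed)
    analytes = list(cfg.marine_conc)
    lines = {a: _mixing_line(cfg, a) for a in analytes}

    stations = [(st, "fjord") for st in cfg.fjord_stations] + \
               [(st, "shelf") for st in cfg.shelf_stations]
    ctd_rows, nut_rows = [], []
    truth_f = {}
    for role in ("fjord", "shelf"):
        members = [s for s, r in stations if r == role]
        offsets = (np.linspace(-cfg.station_spread, cfg.station_spread,
                               len(members)) if len(members) > 1
                   else np.zeros(1))
        for st, off in zip(members, offsets):
            for layer in cfg.layers:
                s = layer[f"s_{role}"] + off
                depth = layer["depth"]
                temp = layer["temp"]
                f = (s - cfg.s_fresh) / (cfg.s_marine - cfg.s_fresh)
                truth_f[(st, depth)] = f
                ctd_rows.append({"station_id": st, "region": cfg.region,
                                 "year": cfg.year, "depth_m": depth,
                                 "temp_c": temp, "sal": s})
                row = {"station_id": st, "region": cfg.region,
                       "year": cfg.year, "depth_m": depth, "sal": s}
                for a in analytes:
                    c = lines[a](s)
                    if role == "fjord" and depth <= cfg.depth_cutoff:
                        c -= cfg.sink_delta
                    if cfg.noise_sd > 0:
                        c += rng.normal(0.0, cfg.noise_sd)
                    if c < 0:
                        c = 0.0
                    row[a] = c
                chl = 1.2 * np.exp(-depth / 40.0)
                if cfg.noise_sd > 0:
                    chl = max(0.0, chl + rng.normal(0.0, cfg.noise_sd / 10))
                row["chl_a"] = chl
                nut_rows.append(row)
    ctd = pd.DataFrame(ctd_rows)
    nutrients = pd.DataFrame(nut_rows)
    truth = {
        "region": cfg.region, "year": cfg.year,
        "endmembers": {"marine": {"s": cfg.s_marine, "conc": cfg.marine_conc},
                       "fresh": {"s": cfg.s_fresh,
                                 "conc": {a: cfg.fresh_conc.get(a, 0.0)
                                          for a in analytes}}},
        "sink_delta": cfg.sink_delta,
        "depth_cutoff": cfg.depth_cutoff,
        "fjord_stations": cfg.fjord_stations,
        "shelf_stations": cfg.shelf_stations,
        "layer_labels": {str(l["depth"]): l["label"] for l in cfg.layers},
        "mixing_fraction": {f"{st}@{d}": f for (st, d), f in truth_f.items()},
    }
    return ctd, nutrients, truth


# --------------------------------------------------------------------------
# Taxa tables
# --------------------------------------------------------------------------

_BASE_TAXONOMY = [
    # asv_id, domain, phylum, class, order, family, genus
    ("asv_b01", "Bacteria", "Proteobacteria", "Gammaproteobacteria",
     "Pseudomonadales", "Pseudomonadaceae", "Pseudomonas"),
    ("asv_b02", "Bacteria", "Proteobacteria", "Alphaproteobacteria",
     "Pelagibacterales", "Pelagibacteraceae", "Pelagibacter"),
    ("asv_b03", "Bacteria", "Bacteroidota", "Bacteroidia",
     "Flavobacteriales", "Flavobacteriaceae", "Polaribacter"),
    ("asv_b04", "Bacteria", "Cyanobacteria", "Cyanobacteriia",
     "Synechococcales", "Cyanobiaceae", "Synechococcus"),
    ("asv_b05", "Bacteria", "Verrucomicrobiota", "Verrucomicrobiae",
     "Verrucomicrobiales", "Rubritaleaceae", "Luteolibacter"),
    ("asv_b06", "Bacteria", "Actinobacteriota", "Acidimicrobiia",
     "Acidimicrobiales", "Ilumatobacteraceae", "Ilumatobacter"),
    ("asv_b07", "Bacteria", "Planctomycetota", "Planctomycetia",
     "Pirellulales", "Pirellulaceae", "Rhodopirellula"),
    ("asv_b08", "Bacteria", "Proteobacteria", "Gammaproteobacteria",
     "Alteromonadales", "Alteromonadaceae", "Alteromonas"),
    ("asv_b09", "Archaea", "Thermoplasmatota", "Thermoplasmata",
     "Marine Group II", None, None),
    ("asv_b10", "Bacteria", None, None, None, None, None),  # phylum-unassigned
]

_NITRIFIER_TAXONOMY = [
    ("asv_aoa1", "Archaea", "Thermoproteota", "Nitrososphaeria",
     "Nitrososphaerales", "Nitrosopumilaceae", "Nitrosopumilus"),
    ("asv_aoa2", "Archaea", "Thermoproteota", "Nitrososphaeria",
     "Nitrososphaerales", "Nitrosopumilaceae", "Nitrosopelagicus"),
    ("asv_aob1", "Bacteria", "Proteobacteria", "Gammaproteobacteria",
     "Burkholderiales", "Nitrosomonadaceae", "Nitrosomonas"),
    ("asv_aob2", "Bacteria", "Proteobacteria", "Gammaproteobacteria",
     "Chromatiales", "Chromatiaceae", "Nitrosococcus"),
    ("asv_nob1", "Bacteria", "Nitrospinota", "Nitrospinia",
     "Nitrospinales", "Nitrospinaceae", "Nitrospina"),
    ("asv_nob2", "Bacteria", "Nitrospirota", "Nitrospiria",
     "Nitrospirales", "Nitrospiraceae", "Nitrospira"),
    ("asv_nob3", "Bacteria", "Proteobacteria", "Gammaproteobacteria",
     "Burkholderiales", "Gallionellaceae", "Nitrotoga"),
    ("asv_nob4", "Bacteria", "Proteobacteria", "Alphaproteobacteria",
     "Rhizobiales", "Xanthobacteraceae", "Nitrobacter"),
]


def default_taxonomy() -> pd.DataFrame:
    rows = _BASE_TAXONOMY + _NITRIFIER_TAXONOMY
    df = pd.DataFrame(rows, columns=["asv_id", "domain", "phylum", "class",
                                     "order", "family", "genus"])
    return df.set_index("asv_id")


@dataclass
class CommunityConfig:
    """Dirichlet-multinomial community model.

    ``compositions`` maps water mass -> mean composition over the base
    (non-nitrifier) ASVs; drawn deterministically from the seed when not
    given.  The nitrifier fraction grows monotonically with depth from
    ``nitrifier_floor`` to ``nitrifier_floor + nitrifier_span``.
    """

    concentration: float = 500.0     # Dirichlet precision
    seq_depth: int = 20000
    compositions: dict[str, np.ndarray] | None = None
    nitrifier_floor: float = 0.02
    nitrifier_span: float = 0.40
    nitrifier_max_depth: float = 400.0
    seed: int = 0

    def nitrifier_fraction(self, depth: float) -> float:
        z = min(depth, self.nitrifier_max_depth) / self.nitrifier_max_depth
        return self.nitrifier_floor + self.nitrifier_span * z


def generate_taxa_table(cfg: CommunityConfig, meta: pd.DataFrame
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts (samples x ASVs) and taxonomy for given sample metadata.

    ``meta`` needs sample_id, water_mass and depth_m columns.  Counts are
    multinomial draws of per-sample Dirichlet compositions; nitrifier ASVs
    receive a depth-increasing share of the community.
    """
    taxonomy = default_taxonomy()
    base_ids = [r[0] for r in _BASE_TAXONOMY]
    nit_ids = [r[0] for r in _NITRIFIER_TAXONOMY]
    rng = np.random.default_rng(cfg.seed)

    wms = list(pd.unique(meta["water_mass"]))
    comps = cfg.compositions
    if comps is None:
        comps = {}
        for wm in sorted(map(str, wms)):
            comps[wm] = rng.dirichlet(np.full(len(base_ids), 0.6))
    for wm in wms:
        if str(wm) not in {str(k) for k in comps}:
            raise ValueError(f"no configured composition for water mass {wm}")
        v = np.asarray(comps[str(wm)] if str(wm) in comps else comps[wm], float)
        if abs(v.sum() - 1.0) > 1e-9 or len(v) != len(base_ids):
            raise ValueError(f"composition for {wm} must sum to 1 over "
                             f"{len(base_ids)} base taxa")

    # fixed relative profile among the nitrifiers (AOA-dominated at depth)
    nit_profile = np.array([0.40, 0.25, 0.08, 0.05, 0.08, 0.05, 0.05, 0.04])
    nit_profile = nit_profile / nit_profile.sum()

    counts = np.zeros((len(meta), len(base_ids) + len(nit_ids)), dtype=int)
    for i, row in enumerate(meta.itertuples(index=False)):
        w = cfg.nitrifier_fraction(float(row.depth_m))
        base = np.asarray(comps[str(row.water_mass)], dtype=float)
        p = np.concatenate([(1.0 - w) * base, w * nit_profile])
        alpha = cfg.concentration * np.clip(p, 1e-12, None)
        probs = rng.dirichlet(alpha)
        counts[i] = rng.multinomial(cfg.seq_depth, probs)
    count_df = pd.DataFrame(counts, index=list(meta["sample_id"]),
                            columns=base_ids + nit_ids)
    count_df.index.name = "sample_id"
    return count_df, taxonomy


# --------------------------------------------------------------------------
# Gene counts
# --------------------------------------------------------------------------

DEFAULT_GENE_LENGTHS = {
    "nifH": 870, "amoA": 820, "amoB": 630, "hao": 1710, "nosZ": 1910,
    "nirK": 1130, "norB": 1390, "hdh": 1600, "napA": 2490, "nirD": 330,
    "narB": 2220, "nasA": 2400, "recA": 1060, "gyrB": 2420, "rpoB": 4030,
}


@dataclass
class GeneSimConfig:
    """Poisson read-count model with known per-genome copy numbers."""

    samples: tuple[str, ...] = ("S1", "S2")
    copy_numbers: dict[str, dict[str, float]] | None = None
    ref_coverage: float = 0.05        # reads per bp for a single-copy gene
    gene_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GENE_LENGTHS))
    references: tuple[str, ...] = ("recA", "gyrB", "rpoB")
    seed: int = 0


def generate_gene_counts(cfg: GeneSimConfig
                         ) -> tuple[pd.DataFrame, dict]:
    """Per (sample, gene) mapped reads ~ Poisson(copy * ref_cov * length).

    Reference genes are generated at copy number 1.  Returns the count
    table and a truth record of the copy numbers used.
    """
    rng = np.random.default_rng(cfg.seed)
    panel_genes = [g for g in cfg.gene_lengths if g not in cfg.references]
    copy_numbers = cfg.copy_numbers
    if copy_numbers is None:
        copy_numbers = {
            s: {g: round(float(rng.uniform(0.0, 2.0)), 3)
                for g in panel_genes}
            for s in cfg.samples
        }
    rows = []
    for sample in cfg.samples:
        for gene, length in cfg.gene_lengths.items():
            copy = 1.0 if gene in cfg.references \
                else float(copy_numbers[sample].get(gene, 0.0))
            lam = copy * cfg.ref_coverage * length
            reads = int(rng.poisson(lam)) if lam > 0 else 0
            rows.append({"sample_id": sample, "gene_symbol": gene,
                         "contig_id": f"ctg_{sample}_{gene}",
                         "mapped_reads": reads, "gene_length_bp": length})
    truth = {"copy_numbers": copy_numbers, "ref_coverage": cfg.ref_coverage}
    return pd.DataFrame(rows), truth


# --------------------------------------------------------------------------
# Full bundle
# --------------------------------------------------------------------------

def generate_full_study(out_dir, seed: int = 0, sink_delta: float = 0.0,
                        noise_sd: float = 0.0) -> dict:
    """Write a coherent two-region, two-year synthetic study to a directory.

    Emits ctd.csv, nutrients.csv, taxa_counts.tsv, taxonomy.tsv,
    sample_meta.tsv, gene_counts.tsv, envelopes.yaml, roles.yaml,
    panel.yaml and truth.json; every downstream CLI runs on the bundle
    unmodified.  Returns the truth record.
    """
    from importlib import resources

    from .io_cli.tables import write_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    regions = ("fjordA", "fjordB")
    years = (2016, 2017)

    ctds, nuts, truths = [], [], {}
    for i, region in enumerate(regions):
        for j, year in enumerate(years):
            cfg = TransectConfig(region=region, year=year,
                                 sink_delta=sink_delta, noise_sd=noise_sd,
                                 seed=seed + 13 * i + 7 * j)
            ctd, nut, truth = generate_profiles(cfg)
            ctds.append(ctd)
            nuts.append(nut)
            truths[f"{region}_{year}"] = truth
    ctd = pd.concat(ctds, ignore_index=True)
    nutrients = pd.concat(nuts, ignore_index=True)

    # community samples: 3 stations x 4 depths per region-year
    meta_rows = []
    layer_label = {l["depth"]: l["label"] for l in DEFAULT_LAYERS}
    for region in regions:
        for year in years:
            key = f"{region}_{year}"
            stations = truths[key]["fjord_stations"][:2] + \
                truths[key]["shelf_stations"][:1]
            for st in stations:
                for depth in (5.0, 50.0, 150.0, 400.0):
                    meta_rows.append({
                        "sample_id": f"{st}_{year}_{int(depth)}",
                        "region": region, "year": year, "depth_m": depth,
                        "water_mass": layer_label[depth],
                    })
    meta = pd.DataFrame(meta_rows)
    ccfg = CommunityConfig(seed=seed + 101)
    counts, taxonomy = generate_taxa_table(ccfg, meta)

    gcfg = GeneSimConfig(samples=tuple(meta["sample_id"][:8]),
                         seed=seed + 202)
    genes, gene_truth = generate_gene_counts(gcfg)

    write_table(ctd, out / "ctd.csv")
    write_table(nutrients, out / "nutrients.csv")
    write_table(meta, out / "sample_meta.tsv")
    write_table(taxonomy.reset_index(), out / "taxonomy.tsv")
    counts_long = counts.reset_index()
    write_table(counts_long, out / "taxa_counts.tsv")
    write_table(genes, out / "gene_counts.tsv")

    for name in ("envelopes.yaml", "gene_panel.yaml"):
        text = resources.files("fjordflux").joinpath(f"data/{name}") \
            .read_text(encoding="utf-8")
        (out / ("panel.yaml" if name == "gene_panel.yaml" else name)
         ).write_text(text, encoding="utf-8")

    pair_list = [["AW", "SW"], ["AW", "IW"], ["AW", "AW"],
                 ["TAW", "SW"], ["TAW", "IW"], ["TAW", "TAW"]]
    roles = {"regions": {
        region: {
            "shelf": truths[f"{region}_{years[0]}"]["shelf_stations"],
            "fjord": truths[f"{region}_{years[0]}"]["fjord_stations"],
            "pairs": {int(y): pair_list for y in years},
        } for region in regions
    }}
    with open(out / "roles.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(roles, fh, sort_keys=True)

    bundle_truth = {"seed": seed, "sink_delta": sink_delta,
                    "noise_sd": noise_sd, "transects": truths,
                    "genes": gene_truth}
    with open(out / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(bundle_truth, fh, indent=1, sort_keys=True)
    return bundle_truth
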