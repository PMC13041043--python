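# File formats

All tables are UTF-8 CSV (`.csv`, comma) or TSV (anything else, tab);
the delimiter is chosen from the extension. Decimal point only. Missing
values are empty cells — tokens such as `n/a` raise a parse error. Floats
are written with 6 significant digits (round trips are exact to ~1e-6
relative).

## CTD table (`ctd.csv`)

One row per (station, depth).

| column      | type  | unit    | notes |
|-------------|-------|---------|-------|
| station_id  | text  |         | |
| region      | text  |         | fjord/transect name |
| year        | int   |         | |
| depth_m     | float | m       | ≥ 0 |
| temp_c      | float | °C      | |
| sal         | float | –       | practical/absolute salinity, ≥ 0 |
| sigma_theta | float | kg m⁻³  | optional; computed from T, S when absent |
| water_mass  | text  |         | optional; added by `fjordflux classify` |

## Nutrient table (`nutrients.csv`)

One row per bottle sample.

Required: `station_id`, `region`, `year`, `depth_m`. Optional analyte
columns (all mmol m⁻³ except `chl_a` in mg m⁻³): `ammonium`,
`nitrate_nitrite`, `nitrite`, `phosphate`, `silicic_acid`, `chl_a`; plus
`sal` (copied from the CTD join when absent) and `water_mass`.

## Sample metadata (`sample_meta.tsv`)

`sample_id`, `region`, `year`, `depth_m`, `water_mass` — one row per
community sample; `sample_id` must match the taxa count table.

## Taxa counts (`taxa_counts.tsv`)

First column `sample_id`, remaining columns one per ASV id, integer read
counts.

## Taxonomy (`taxonomy.tsv`)

`asv_id`, `domain`, `phylum`, `class`, `order`, `family`, `genus`;
`domain` is required, deeper ranks may be empty.

## Gene counts (`gene_counts.tsv`)

`sample_id`, `gene_symbol`, `contig_id` (optional), `mapped_reads` (int),
`gene_length_bp` (int > 0). Multiple rows per (sample, gene) are pooled as
total reads / total length.

## Envelope config (`envelopes.yaml`)

```yaml
sigma_threshold: 27.92        # kg m^-3, density exception for AW/TAW
precedence: [WCW, ArW, LW, SW, IW, TAW, AW]   # multi-match tie-break
envelopes:
  AW: {t_min: 3.0, s_min: 34.9, sigma_max: 27.92}
  # t_min/t_max (°C), s_min/s_max, sigma_max; omitted edges are unbounded.
  # Lower bounds closed, upper bounds open; override per edge with
  # closed: {s_max: true}
```

## Station roles (`roles.yaml`)

```yaml
regions:
  fjordA:
    shelf: [fjordA-X1, fjordA-X2]
    fjord: [fjordA-F1, fjordA-F2]
    pairs:                      # shelf water mass vs fjord water mass
      2016: [[AW, SW], [AW, IW], [AW, AW]]
```

## Gene panel (`panel.yaml`)

```yaml
references: [recA, gyrB, rpoB]  # single-copy normalization genes
genes:
  amoA: nitrification           # gene symbol -> process label
```
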