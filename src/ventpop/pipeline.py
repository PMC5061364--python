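"""End-to-end orchestration, geographic utilities and abundance arithmetic.

Besides wiring the analysis stages together (QC -> diversity ->
demography -> divergence -> networks), this module carries the two small
derived-quantity calculators of the study design: great-circle distances
between vent sites from degree-minute coordinates, and abundance
extrapolation from 64 cm^2 settlement-device counts to per-square-metre
and per-vent-field individual numbers.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import demography, diversity, divergence, haplonet, io_align
from .io_align import MIN_SAMPLE
from .synthetic_data import SynthConfig, simulate_alignment

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class GeoPoint:
    """Signed decimal degrees; south and west are negative."""

    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"latitude out of range: {self.lat}")
        if not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"longitude out of range: {self.lon}")

    @staticmethod
    def parse_coord(token: str) -> tuple[float, str]:
        m = re.fullmatch(
            r"\s*(\d+)\s*°\s*(\d+(?:[.,]\d+)?)\s*'?\s*([NSEW])\s*", token
        )
        if not m:
            raise ValueError(f"unparseable coordinate: {token!r}")
        deg, minutes, hemi = m.groups()
        value = float(deg) + float(minutes.replace(",", ".")) / 60.0
        if hemi in "SW":
            value = -value
        return value, hemi

    @classmethod
    def parse(cls, lat_token: str, lon_token: str) -> "GeoPoint":
        lat, hemi_lat = cls.parse_coord(lat_token)
        lon, hemi_lon = cls.parse_coord(lon_token)
        if hemi_lat not in "NS":
            raise ValueError(f"expected N/S latitude, got {lat_token!r}")
        if hemi_lon not in "EW":
            raise ValueError(f"expected E/W longitude, got {lon_token!r}")
        return cls(lat=lat, lon=lon)


def intersite_distance(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle (haversine) distance in km on a sphere of R = 6371 km."""
    la1, lo1, la2, lo2 = map(math.radians, (a.lat, a.lon, b.lat, b.lon))
    h = (
        math.sin((la2 - la1) / 2) ** 2
        + math.cos(la1) * math.cos(la2) * math.sin((lo2 - lo1) / 2) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * math.asin(math.sqrt(h))


SETTLEMENT_DEVICE_CM2 = 64.0


def density_per_m2(mean_per_64cm2: float) -> float:
    """Individuals per m^2 from a mean count per 64 cm^2 device."""
    if mean_per_64cm2 <= 0:
        raise ValueError("abundance must be positive")
    return mean_per_64cm2 * 1e4 / SETTLEMENT_DEVICE_CM2


def density_extrapolation(mean_per_64cm2: float, area_m2: float) -> float:
    """Expected individuals on ``area_m2`` of vent field."""
    if area_m2 <= 0:
        raise ValueError("area must be positive")
    return density_per_m2(mean_per_64cm2) * area_m2


# ---------------------------------------------------------------------------
# Pipeline


@dataclass
class RunConfig:
    """Configuration of one end-to-end run (echoed into the output)."""

    out_dir: str = "ventpop-out"
    input_fasta: str | None = None
    sample_sheet: str | None = None
    synth: dict | None = None        # SynthConfig kwargs per population
    frame_offset: int = 0
    genetic_code: int = 5
    seed: int = 0
    reps_demography: int = 1000
    reps_permutation: int = 1000
    network_alpha: float = 0.95
    run_im_study: bool = False
    im_study: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls(**data)


def _load_or_generate(config: RunConfig, rng: np.random.Generator):
    if config.input_fasta:
        records = io_align.read_fasta(config.input_fasta)
        if config.sample_sheet:
            sheet = io_align.read_sample_sheet(config.sample_sheet)
            records = io_align.attach_metadata(records, sheet)
        else:
            sheet = pd.DataFrame(
                [
                    {"id": r.id, "species": r.species,
                     "region": r.region, "site": r.site}
                    for r in records
                ]
            )
        aln = io_align.CodonAlignment(records, config.frame_offset,
                                      config.genetic_code)
        return aln, sheet
    # synthetic input: one or more populations of one synthetic species
    synth = dict(config.synth or {})
    sites = synth.pop("sites", {"sim-A": 20, "sim-B": 20})
    records = []
    for site, n in sites.items():
        sc = SynthConfig(n=n, site=site,
                         seed=int(rng.integers(2**31 - 1)), **synth)
        sub = simulate_alignment(sc)
        for r in sub.records:
            r = io_align.SequenceRecord(f"{site}_{r.id}", r.seq, r.species,
                                        r.region, r.site)
            records.append(r)
    aln = io_align.CodonAlignment(records, 0, config.genetic_code)
    sheet = pd.DataFrame(
        [{"id": r.id, "species": r.species, "region": r.region,
          "site": r.site} for r in records]
    )
    return aln, sheet


def run_pipeline(config: RunConfig) -> dict:
    """QC, per-population statistics, F_ST and networks in one run.

    Writes TSV tables mirroring the standard diversity/demography table
    layouts, a per-species F_ST table, GraphML networks, and a JSON log
    with the seeds of every stochastic stage.  Deterministic given
    ``config.seed``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    seeds = {
        "input": int(rng.integers(2**31 - 1)),
        "demography": int(rng.integers(2**31 - 1)),
        "permutation": int(rng.integers(2**31 - 1)),
        "sharing": int(rng.integers(2**31 - 1)),
    }
    aln, sheet = _load_or_generate(config,
                                   np.random.default_rng(seeds["input"]))

    qc = io_align.screen_orf(aln)
    io_align.write_qc_report(qc, out / "qc_report.tsv")
    passed = {r.id for r in qc if r.passed}
    aln = aln.subset([i for i in aln.ids() if i in passed])
    sheet = sheet[sheet["id"].isin(passed)]

    div_rows, dem_rows, pops_by_species = [], [], {}
    combos = sheet[["species", "site"]].drop_duplicates()
    for k, (species, site) in enumerate(combos.itertuples(index=False)):
        pop = io_align.subsample_population(aln, sheet, species, site)
        pops_by_species.setdefault(species, []).append(pop)
        div_rows.append(diversity.diversity_summary(pop))
        dem_rows.append(
            demography.demography_summary(
                pop, reps=config.reps_demography,
                seed=seeds["demography"] + k,
            )
        )
    diversity.diversity_table(div_rows).to_csv(
        out / "diversity.tsv", sep="\t", index=False
    )
    demography.demography_table(dem_rows).to_csv(
        out / "demography.tsv", sep="\t", index=False
    )

    fst_rows = []
    for species, pops in pops_by_species.items():
        usable = [p for p in pops if p.n >= MIN_SAMPLE]
        if len(usable) < 2:
            continue
        ids = [i for p in usable for i in p.alignment.ids()]
        mask = io_align.complete_sites(aln, ids)
        shared = [
            io_align.PopulationSample(p.alignment, mask, p.species,
                                      p.region, p.site)
            for p in usable
        ]
        res = divergence.permutation_test(
            shared, reps=config.reps_permutation, seed=seeds["permutation"]
        )
        fst_rows.append(
            {"species": species,
             "populations": ";".join(f"{s}:{n}" for s, n in res.populations),
             "fst": res.fst, "p_value": res.p_value,
             "n_perm": res.n_permutations}
        )
    pd.DataFrame(
        fst_rows, columns=["species", "populations", "fst", "p_value", "n_perm"]
    ).to_csv(out / "fst.tsv", sep="\t", index=False)

    for species, pops in pops_by_species.items():
        ids = [i for p in pops for i in p.alignment.ids()]
        mask = io_align.complete_sites(aln, ids)
        merged = io_align.PopulationSample(aln.subset(ids), mask, species)
        table = diversity.collapse_haplotypes(merged)
        tag = re.sub(r"\W+", "_", species)
        haplonet.write_haplotype_table(table, out / f"haplotypes_{tag}.tsv")
        net = haplonet.build_network(table, alpha=config.network_alpha)
        haplonet.write_graphml(net, out / f"network_{tag}.graphml")

    log = {"config": asdict(config), "seeds": seeds,
           "n_sequences": len(aln), "n_passed_qc": len(passed)}
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return {"out_dir": str(out), "seeds": seeds,
            "n_populations": len(div_rows), "n_fst": len(fst_rows)}
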