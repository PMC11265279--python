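"""Synthetic cheese-surface virome communities with recorded ground truth.

The generator emulates the statistical structure the analysis assumes: a
guild-structured phage community over five ripening stages (a stable
starter-phage guild, a declining guild, rising ripening-phage guilds and a
sporadic low-abundance tail), triplicate sampling, compositional count
sampling with Dirichlet overdispersion, a correlated bacterial genus table
(constant lactic acid bacteria, ~2-log aerobic growth), and a long-term arm
in which one genome pool persists across three production years with
year-specific sporadic membership.

On the sequence side it plants species clusters (member copies at a stated
substitution rate), outgroups, chimeras (internal duplications), sub-size
fragments, non-viral contigs and a PhiX174 sequencing-control decoy, and
emits tool reports that exercise the catalog's selection rules. Every
generated contig and every planted effect is recorded in a
:class:`SyntheticTruth` so recovery can be measured exactly.

All generators are pure functions of (design, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .io import (
    REPLICATES,
    STAGES,
    YEARS,
    ContigRecord,
    CountMatrix,
    DairyPhageDB,
    DairyPhageEntry,
    SampleFrame,
    ToolReport,
)

logger = logging.getLogger("rindvirome")

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class GuildSpec:
    """One phage guild: a set of vOTUs sharing hosts and stage dynamics.

    ``rate`` is the per-stage multiplicative change for declining guilds
    and the total fold change between the {W1,W2} and {W4,W5} stage-group
    means for rising guilds (the rise follows a logistic curve centred on
    ``rise_midpoint``).
    """

    name: str
    n_votus: int
    dynamic: str  # stable | declining | rising | sporadic
    base_fraction: float
    rate: float = 1.0
    host_genus: str | None = None
    phage_group: str | None = None
    rise_midpoint: float = 3.0

    def __post_init__(self) -> None:
        if self.dynamic not in ("stable", "declining", "rising", "sporadic"):
            raise ValueError(f"unknown guild dynamic {self.dynamic!r}")
        if self.rate <= 0:
            raise ValueError("guild rate must be > 0")


@dataclass
class CommunityDesign:
    """Full parameterization of one synthetic study (short- and long-term arms)."""

    guilds: list[GuildSpec] = field(default_factory=lambda: default_guilds())
    n_stages: int = 5
    n_replicates: int = 3
    n_years: int = 3
    library_log10_mean: float = 5.0
    library_log10_sd: float = 0.15
    theta: float = 200.0            # Dirichlet concentration (replicate overdispersion)
    # year-level composition redraw: concentration high enough that shared
    # (non-sporadic) vOTUs fluctuate between years without going extinct
    year_theta: float = 2_000.0
    seed: int = 0
    # sequence-level knobs
    length_range: tuple[int, int] = (2_000, 150_000)
    member_rate: float = 0.03       # per-base substitution rate of same-species copies
    outgroup_rate: float = 0.25     # rate producing a distinct species
    p_members: float = 0.4          # fraction of vOTUs receiving 1-3 member copies
    max_members: int = 3
    n_outgroups: int = 5
    n_chimeras: int = 3
    n_fragments: int = 4
    n_nonviral: int = 8
    temperate_fraction: float = 0.08
    iphop_error_rate: float = 0.1
    iphop_missing_rate: float = 0.1
    dairy_db_size: int = 10
    dairy_db_rate: float = 0.02     # divergence of db relatives from their vOTU
    sporadic_year_presence: float = 0.45
    within_guild_level_sd: float = 0.35  # lognormal sigma of per-vOTU weights (natural log)
    plate_noise_sd: float = 0.1     # sd of plate-count noise, log10 CFU/g

    def __post_init__(self) -> None:
        if not self.guilds:
            raise ValueError("design must contain at least one guild")
        total = sum(g.base_fraction for g in self.guilds)
        if total > 1 + 1e-9:
            raise ValueError(f"guild base fractions sum to {total:.3f} > 1")
        if self.theta <= 0 or not np.isfinite(self.theta):
            raise ValueError("theta must be positive and finite")

    @property
    def n_votus(self) -> int:
        return sum(g.n_votus for g in self.guilds)


def default_guilds() -> list[GuildSpec]:
    """Default community: starter-phage decline, ripening-phage rise.

    Mirrors the observed succession of a smear-ripened cheese surface at
    desk scale. The abundant band holds the stable Lactococcus 936/949
    guilds together with an abundant declining P335-like guild (planted
    log2FC = 3 log2(rate) = -4 exactly; abundant so it clears the
    mean-raw-count gate of the differential test). Two ripening guilds
    rise 16-fold from low starting shares (planted log2FC = +4), a late
    Pseudoalteromonas-like guild climbs from the detection floor only in
    the final stages, a low declining guild fades to the floor, and a
    sporadic tail turns over between production years. The profile
    classes this plants for the heatmap clustering are: abundant band,
    low-declining, rising, late-rising, and detection-floor — five
    clusters, mirroring a ripening succession.
    """
    return [
        GuildSpec("stable_936", 16, "stable", 0.26, host_genus="Lactococcus", phage_group="936"),
        GuildSpec("stable_949", 8, "stable", 0.13, host_genus="Lactococcus", phage_group="949"),
        GuildSpec("declining_P335", 5, "declining", 0.45, rate=2 ** (-4 / 3),
                  host_genus="Lactococcus", phage_group="P335"),
        GuildSpec("declining_low", 8, "declining", 0.04, rate=2 ** (-5 / 3),
                  host_genus="Streptococcus", phage_group="987"),
        GuildSpec("rising_glutamicibacter", 4, "rising", 0.006, rate=16.0,
                  host_genus="Glutamicibacter", phage_group="Montesquieu", rise_midpoint=2.75),
        GuildSpec("rising_brevibacterium", 4, "rising", 0.006, rate=16.0,
                  host_genus="Brevibacterium", phage_group="Rousseau", rise_midpoint=2.75),
        GuildSpec("late_pseudoalteromonas", 8, "rising", 0.0024, rate=32.0,
                  host_genus="Pseudoalteromonas", phage_group=None, rise_midpoint=4.3),
        GuildSpec("sporadic_low", 12, "sporadic", 0.0024),
        GuildSpec("sporadic_rare", 35, "sporadic", 0.0007),
    ]


#: planted profile-cluster class per default guild (used by recovery tests)
DEFAULT_PROFILE_CLASSES = {
    "stable_936": "abundant_band",
    "stable_949": "abundant_band",
    "declining_P335": "abundant_band",
    "declining_low": "low_declining",
    "rising_glutamicibacter": "rising",
    "rising_brevibacterium": "rising",
    "late_pseudoalteromonas": "late_rising",
    "sporadic_low": "floor",
    "sporadic_rare": "floor",
}


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated study.

    ``contigs`` has one row per generated contig (cluster id, chimera /
    viral / fragment / PhiX flags, guild, host, lifestyle); ``votus`` has
    one row per planted vOTU including the expected log2 fold change
    between the {W1,W2} and {W4,W5} stage-group means.
    """

    contigs: pd.DataFrame
    votus: pd.DataFrame

    def __post_init__(self) -> None:
        if self.contigs["contig_id"].duplicated().any():
            raise ValueError("duplicate contig ids in truth")

    def cluster_of(self, contig_id: str) -> str:
        return self.contigs.set_index("contig_id").loc[contig_id, "cluster_id"]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "contigs": self.contigs.to_dict(orient="records"),
            "votus": self.votus.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=1, default=str))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(pd.DataFrame(payload["contigs"]), pd.DataFrame(payload["votus"]))


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, length)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitution-only mutation at a fixed per-base rate (no indels)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    if hit.size:
        base_idx = np.zeros(256, dtype=np.int64)
        for i, b in enumerate(b"ACGT"):
            base_idx[b] = i
        shift = rng.integers(1, 4, hit.size)
        new_idx = (base_idx[arr[hit]] + shift) % 4
        arr[hit] = np.frombuffer(b"ACGT", dtype=np.uint8)[new_idx]
    return arr.tobytes().decode("ascii")


def generate_genomes(
    design: CommunityDesign, rng: np.random.Generator | None = None
) -> tuple[list[ContigRecord], SyntheticTruth]:
    """Plant reference genomes, member/outgroup copies, chimeras, fragments and decoys."""
    rng = np.random.default_rng(design.seed) if rng is None else rng
    contigs: list[ContigRecord] = []
    contig_rows: list[dict] = []
    votu_rows: list[dict] = []

    lo, hi = design.length_range
    votu_idx = 0
    temperate_draw = rng.random(design.n_votus) < design.temperate_fraction
    for guild in design.guilds:
        for _ in range(guild.n_votus):
            votu_id = f"votu_{votu_idx:03d}"
            length = int(np.round(np.exp(rng.uniform(np.log(lo + 2), np.log(hi)))))
            seq = _random_seq(rng, length)
            lifestyle = "temperate" if temperate_draw[votu_idx] else "virulent_or_unknown"
            contigs.append(ContigRecord(f"{votu_id}_c0", seq))
            contig_rows.append(
                dict(contig_id=f"{votu_id}_c0", cluster_id=votu_id, is_chimera=False,
                     is_viral=True, is_fragment=False, is_phix=False, guild=guild.name,
                     host_genus=guild.host_genus, lifestyle=lifestyle)
            )
            votu_rows.append(
                dict(votu_id=votu_id, guild=guild.name, dynamic=guild.dynamic,
                     host_genus=guild.host_genus, phage_group=guild.phage_group,
                     lifestyle=lifestyle, length=length)
            )
            if rng.random() < design.p_members:
                for m in range(rng.integers(1, design.max_members + 1)):
                    contigs.append(
                        ContigRecord(f"{votu_id}_m{m + 1}", _mutate(rng, seq, design.member_rate))
                    )
                    contig_rows.append(
                        dict(contig_id=f"{votu_id}_m{m + 1}", cluster_id=votu_id,
                             is_chimera=False, is_viral=True, is_fragment=False,
                             is_phix=False, guild=guild.name, host_genus=guild.host_genus,
                             lifestyle=lifestyle)
                    )
            votu_idx += 1

    # outgroups: heavily diverged copies of existing genomes -> distinct species
    ref_ids = [r["votu_id"] for r in votu_rows]
    for i, src in enumerate(rng.choice(ref_ids, size=min(design.n_outgroups, len(ref_ids)), replace=False)):
        src_seq = next(c.sequence for c in contigs if c.id == f"{src}_c0")
        cid = f"outgroup_{i:02d}"
        contigs.append(ContigRecord(cid, _mutate(rng, src_seq, design.outgroup_rate)))
        contig_rows.append(
            dict(contig_id=cid, cluster_id=cid, is_chimera=False, is_viral=True,
                 is_fragment=False, is_phix=False, guild="outgroup", host_genus=None,
                 lifestyle="virulent_or_unknown")
        )

    # chimeras: a genome with its own first half appended (self-alignment > 110%)
    for i in range(design.n_chimeras):
        g = _random_seq(rng, int(rng.integers(6_000, 20_000)))
        cid = f"chimera_{i:02d}"
        contigs.append(ContigRecord(cid, g + g[: len(g) // 2]))
        contig_rows.append(
            dict(contig_id=cid, cluster_id=cid, is_chimera=True, is_viral=True,
                 is_fragment=False, is_phix=False, guild="chimera", host_genus=None,
                 lifestyle="virulent_or_unknown")
        )

    # sub-threshold fragments (< 2 kb)
    for i in range(design.n_fragments):
        cid = f"fragment_{i:02d}"
        contigs.append(ContigRecord(cid, _random_seq(rng, int(rng.integers(500, 2_000)))))
        contig_rows.append(
            dict(contig_id=cid, cluster_id=cid, is_chimera=False, is_viral=True,
                 is_fragment=True, is_phix=False, guild="fragment", host_genus=None,
                 lifestyle="virulent_or_unknown")
        )

    # non-viral (host / plasmid-like) contigs
    for i in range(design.n_nonviral):
        cid = f"nonviral_{i:02d}"
        contigs.append(ContigRecord(cid, _random_seq(rng, int(rng.integers(2_500, 50_000)))))
        contig_rows.append(
            dict(contig_id=cid, cluster_id=cid, is_chimera=False, is_viral=False,
                 is_fragment=False, is_phix=False, guild="nonviral", host_genus=None,
                 lifestyle="virulent_or_unknown")
        )

    # PhiX174 sequencing-control decoy (genome length of the real control)
    contigs.append(ContigRecord("PhiX174", _random_seq(rng, 5_386)))
    contig_rows.append(
        dict(contig_id="PhiX174", cluster_id="PhiX174", is_chimera=False, is_viral=True,
             is_fragment=False, is_phix=True, guild="decoy", host_genus=None,
             lifestyle="virulent_or_unknown")
    )

    truth = SyntheticTruth(pd.DataFrame(contig_rows), pd.DataFrame(votu_rows))
    logger.info(
        "generated %d contigs for %d planted vOTUs (%d guilds)",
        len(contigs), len(votu_rows), len(design.guilds),
    )
    return contigs, truth


# ---------------------------------------------------------------------------
# dynamics and counts
# ---------------------------------------------------------------------------

def _rising_curve(n_stages: int, fold: float, midpoint: float) -> np.ndarray:
    """Logistic trajectory whose {W4,W5} over {W1,W2} mean ratio equals ``fold``."""
    stages = np.arange(1, n_stages + 1, dtype=float)

    def ratio(a: float) -> float:
        f = expit(a * (stages - midpoint))
        return (f[3] + f[4]) / (f[0] + f[1])

    if fold <= 1:
        raise ValueError("rising guilds need fold > 1")
    if ratio(50.0) <= fold:
        raise ValueError(
            f"rise_midpoint={midpoint} cannot reach a {fold}-fold increase "
            "between the early and late stage-group means (midpoint too early/late)"
        )
    a = brentq(lambda x: ratio(x) - fold, 1e-3, 50.0)
    return expit(a * (stages - midpoint))


def generate_dynamics(
    design: CommunityDesign, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Expected relative-abundance tensor (stage x vOTU) plus planted log2FCs.

    Guild trajectories: stable = constant; declining = rate**(stage-1);
    rising = logistic calibrated so the {W4,W5}/{W1,W2} mean ratio equals
    the guild's fold; sporadic = constant low level (its year-to-year
    turnover lives in the long-term arm). Within a guild, per-vOTU weights
    are lognormal. Each stage vector is renormalized to sum to 1; the
    planted log2FC is recorded *before* renormalization, i.e. on the guild
    trajectory scale shared by all of a guild's vOTUs.
    """
    rng = np.random.default_rng(design.seed + 1) if rng is None else rng
    stages = np.arange(1, design.n_stages + 1, dtype=float)
    cols: dict[str, np.ndarray] = {}
    lfc: dict[str, float] = {}
    for guild in design.guilds:
        if guild.dynamic == "declining":
            traj = guild.rate ** (stages - 1)
        elif guild.dynamic == "rising":
            traj = _rising_curve(design.n_stages, guild.rate, guild.rise_midpoint)
        else:  # stable or sporadic
            traj = np.ones_like(stages)
        traj = traj / traj[0]  # base_fraction anchors the W1 share
        expected_lfc = float(np.log2((traj[3] + traj[4]) / (traj[0] + traj[1])))
        weights = rng.lognormal(0.0, design.within_guild_level_sd, guild.n_votus)
        weights = weights / weights.sum()
        for w in weights:
            votu_id = f"votu_{len(cols):03d}"
            cols[votu_id] = guild.base_fraction * w * traj
            lfc[votu_id] = expected_lfc
    table = pd.DataFrame(cols, index=[f"W{s}" for s in range(1, design.n_stages + 1)])
    table = table.div(table.sum(axis=1), axis=0)  # per-stage renormalization
    return table, pd.Series(lfc, name="expected_log2fc")


def _dirichlet(rng: np.random.Generator, alpha: np.ndarray) -> np.ndarray:
    """Dirichlet draw tolerating structural zeros in the mean vector."""
    out = np.zeros_like(alpha, dtype=float)
    pos = alpha > 0
    gam = rng.gamma(alpha[pos])
    if gam.sum() == 0:  # pathological tiny-alpha underflow
        gam = np.ones(pos.sum())
    out[pos] = gam / gam.sum()
    return out


def sample_counts(
    expected: pd.DataFrame,
    design: CommunityDesign,
    rng: np.random.Generator | None = None,
    group_labels: list[str] | None = None,
    study: str = "short_term",
) -> tuple[CountMatrix, SampleFrame]:
    """Draw raw count tables: Dirichlet composition, lognormal library, multinomial reads."""
    if design.theta <= 0:
        raise ValueError("theta must be > 0")
    rng = np.random.default_rng(design.seed + 2) if rng is None else rng
    groups = group_labels if group_labels is not None else list(expected.index)
    rows, meta_rows = {}, []
    for group in groups:
        mean = expected.loc[group].to_numpy()
        for rep in REPLICATES[: design.n_replicates]:
            comp = _dirichlet(rng, design.theta * mean)
            library = int(np.round(10 ** rng.normal(design.library_log10_mean, design.library_log10_sd)))
            sample_id = f"{group}{rep}"
            rows[sample_id] = rng.multinomial(library, comp)
            meta_rows.append(dict(sample_id=sample_id, study=study, group=group, replicate=rep))
    counts = CountMatrix(
        pd.DataFrame.from_dict(rows, orient="index", columns=list(expected.columns)), "raw"
    )
    meta = SampleFrame(pd.DataFrame(meta_rows))
    return counts, meta


def generate_year_dynamics(
    design: CommunityDesign,
    expected: pd.DataFrame,
    votus: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expected composition per production year (long-term arm).

    One genome pool persists across years; the year effect is (a) on/off
    membership of the sporadic guild per year and (b) a year-level
    Dirichlet redraw of the final-stage composition (abundance
    fluctuation of the shared core). Returns the year x vOTU expected
    table and a year x vOTU presence table (the planted persistence
    truth).
    """
    rng = np.random.default_rng(design.seed + 3) if rng is None else rng
    base = expected.iloc[-1].to_numpy()  # post-ripening composition
    sporadic = (votus["dynamic"] == "sporadic").to_numpy()
    years = list(YEARS[: design.n_years])
    rows, presence = {}, {}
    for year in years:
        present = np.ones(base.size, dtype=bool)
        present[sporadic] = rng.random(sporadic.sum()) < design.sporadic_year_presence
        mean = np.where(present, base, 0.0)
        mean = mean / mean.sum()
        rows[year] = _dirichlet(rng, design.year_theta * mean)
        presence[year] = present
    expected_years = pd.DataFrame.from_dict(rows, orient="index", columns=list(expected.columns))
    presence_df = pd.DataFrame.from_dict(presence, orient="index", columns=list(expected.columns))
    return expected_years, presence_df


# ---------------------------------------------------------------------------
# bacteriome
# ---------------------------------------------------------------------------

def generate_bacteriome(
    design: CommunityDesign, rng: np.random.Generator | None = None
) -> tuple[CountMatrix, pd.DataFrame]:
    """Correlated bacterial genus table and plate counts for the short-term arm.

    Absolute abundances: the LAB genus (Lactococcus) stays at 1e8 CFU/g;
    total aerobic ripening bacteria grow log-linearly from 1e8 to 1e10
    across W1..W5, partitioned among the host genera of the rising phage
    guilds (plus Psychrobacter as an extra ripening genus). The genus table
    is the per-sample total-sum scaling of the absolutes; plate counts are
    log10 of the LAB and aerobic totals plus Gaussian noise.
    """
    rng = np.random.default_rng(design.seed + 4) if rng is None else rng
    rising_hosts = sorted(
        {g.host_genus for g in design.guilds if g.dynamic == "rising" and g.host_genus}
    )
    aerobic_genera = rising_hosts + ["Psychrobacter"]
    stages = np.arange(design.n_stages, dtype=float)
    aerobic_total = 10 ** (8.0 + 2.0 * stages / (design.n_stages - 1))
    shares = rng.dirichlet(np.full(len(aerobic_genera), 20.0))

    rows, plate_rows = {}, []
    for s, stage in enumerate(STAGES[: design.n_stages]):
        for rep in REPLICATES[: design.n_replicates]:
            jitter = rng.lognormal(0.0, 0.05, len(aerobic_genera) + 1)
            lab = 1e8 * jitter[0]
            aerobes = aerobic_total[s] * shares * jitter[1:]
            absolute = np.concatenate([[lab], aerobes])
            sample_id = f"{stage}{rep}"
            rows[sample_id] = absolute / absolute.sum()
            plate_rows.append(
                dict(
                    sample_id=sample_id,
                    lab_log10=np.log10(lab) + rng.normal(0.0, design.plate_noise_sd),
                    aerobic_log10=np.log10(aerobes.sum()) + rng.normal(0.0, design.plate_noise_sd),
                )
            )
    genera = ["Lactococcus"] + aerobic_genera
    genus_rel = CountMatrix(pd.DataFrame.from_dict(rows, orient="index", columns=genera), "relative")
    return genus_rel, pd.DataFrame(plate_rows)


# ---------------------------------------------------------------------------
# tool reports
# ---------------------------------------------------------------------------

_GENUS_POOL = [
    "Lactococcus", "Leuconostoc", "Glutamicibacter", "Brevibacterium",
    "Psychrobacter", "Pseudoalteromonas", "Vibrio", "Streptococcus",
]


def generate_tool_reports(
    truth: SyntheticTruth,
    design: CommunityDesign,
    rng: np.random.Generator | None = None,
) -> dict[str, ToolReport]:
    """Emulated VIBRANT/CheckV/VirSorter2/iPHoP labels consistent with the truth.

    Every viral contig gets at least one qualifying label (complete / high /
    medium from VIBRANT or CheckV, or "full" from VirSorter2); non-viral
    contigs get only non-qualifying labels. Temperate contigs carry
    vibrant_lifestyle=temperate. iPHoP genera follow the truth host with a
    configurable error rate, exercising the dairy-match host override.
    """
    rng = np.random.default_rng(design.seed + 5) if rng is None else rng
    reports: dict[str, ToolReport] = {}
    for row in truth.contigs.itertuples(index=False):
        if row.is_viral:
            route = rng.choice(["checkv", "vibrant", "virsorter"], p=[0.6, 0.3, 0.1])
            checkv = vibrant = None
            virsorter = None
            if route == "checkv":
                checkv = str(rng.choice(["complete", "high", "medium"], p=[0.12, 0.08, 0.8]))
                vibrant = str(rng.choice(["medium", "low", "not_determined"]))
            elif route == "vibrant":
                vibrant = str(rng.choice(["complete", "high", "medium"], p=[0.1, 0.2, 0.7]))
                checkv = str(rng.choice(["low", "not_determined"]))
            else:
                virsorter = "full"
                checkv = "low"
                vibrant = "not_determined"
            lifestyle = "temperate" if row.lifestyle == "temperate" else str(rng.choice(["lytic", "lytic", "lytic"]))
        else:
            checkv = str(rng.choice(["low", "not_determined"]))
            vibrant = "low" if rng.random() < 0.5 else None
            virsorter = None
            lifestyle = None
        host = row.host_genus
        iphop = None
        if host is not None and not (isinstance(host, float) and np.isnan(host)):
            if rng.random() >= design.iphop_missing_rate:
                if rng.random() < design.iphop_error_rate:
                    others = [g for g in _GENUS_POOL if g != host]
                    iphop = str(rng.choice(others))
                else:
                    iphop = str(host)
        reports[row.contig_id] = ToolReport(
            contig_id=row.contig_id,
            vibrant_quality=vibrant,
            vibrant_lifestyle=lifestyle,
            checkv_quality=checkv,
            virsorter2_label=virsorter,
            iphop_genus=iphop,
        )
    return reports


def generate_dairy_db(
    truth: SyntheticTruth,
    contigs: list[ContigRecord],
    design: CommunityDesign,
    rng: np.random.Generator | None = None,
) -> DairyPhageDB:
    """A dairy-phage reference catalog containing close relatives of planted vOTUs.

    Entries are lightly diverged copies of reference genomes of the
    non-sporadic guilds (preferring declining and rising guilds so the
    host-override rule is exercised on the ecologically interesting vOTUs).
    """
    rng = np.random.default_rng(design.seed + 6) if rng is None else rng
    seq_by_id = {c.id: c.sequence for c in contigs}
    candidates = truth.votus[truth.votus["dynamic"] != "sporadic"].copy()
    order = candidates["dynamic"].map({"rising": 0, "declining": 1, "stable": 2})
    candidates = candidates.assign(_o=order).sort_values(["_o", "votu_id"])
    chosen = candidates.head(design.dairy_db_size)
    entries, sources = [], []
    for i, row in enumerate(chosen.itertuples(index=False)):
        ref = seq_by_id[f"{row.votu_id}_c0"]
        entries.append(
            DairyPhageEntry(
                name=f"dairyphage_{i:02d}_{row.phage_group}",
                sequence=_mutate(rng, ref, design.dairy_db_rate),
                host_genus=row.host_genus,
                phage_group=row.phage_group,
                lifestyle="temperate" if row.lifestyle == "temperate" else "virulent",
            )
        )
        sources.append(row.votu_id)
    return DairyPhageDB(entries), sources


# ---------------------------------------------------------------------------
# whole-study bundle
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    design: CommunityDesign
    contigs: list[ContigRecord]
    truth: SyntheticTruth
    reports: dict[str, ToolReport]
    dairy_db: DairyPhageDB
    expected_stages: pd.DataFrame
    counts_short: CountMatrix
    meta_short: SampleFrame
    counts_long: CountMatrix
    meta_long: SampleFrame
    year_presence: pd.DataFrame
    genus_rel: CountMatrix
    plate_counts: pd.DataFrame

    @property
    def votu_lengths(self) -> pd.Series:
        return self.truth.votus.set_index("votu_id")["length"].astype(float)


def simulate_study(design: CommunityDesign | None = None, seed: int | None = None) -> SimulatedStudy:
    """Generate a complete synthetic study (sequences, reports, counts, bacteriome)."""
    design = CommunityDesign() if design is None else design
    if seed is not None:
        design = CommunityDesign(**{**asdict_shallow(design), "seed": seed})
    contigs, truth = generate_genomes(design)
    expected, lfc = generate_dynamics(design)
    truth.votus["expected_log2fc"] = truth.votus["votu_id"].map(lfc)
    counts_short, meta_short = sample_counts(expected, design)
    expected_years, presence = generate_year_dynamics(design, expected, truth.votus)
    counts_long, meta_long = sample_counts(
        expected_years, design,
        rng=np.random.default_rng(design.seed + 7),
        group_labels=list(expected_years.index),
        study="long_term",
    )
    genus_rel, plate = generate_bacteriome(design)
    reports = generate_tool_reports(truth, design)
    db, db_sources = generate_dairy_db(truth, contigs, design)
    truth.votus["in_dairy_db"] = truth.votus["votu_id"].isin(db_sources)
    return SimulatedStudy(
        design=design,
        contigs=contigs,
        truth=truth,
        reports=reports,
        dairy_db=db,
        expected_stages=expected,
        counts_short=counts_short,
        meta_short=meta_short,
        counts_long=counts_long,
        meta_long=meta_long,
        year_presence=presence,
        genus_rel=genus_rel,
        plate_counts=plate,
    )


def asdict_shallow(design: CommunityDesign) -> dict:
    d = dict(design.__dict__)
    return d
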