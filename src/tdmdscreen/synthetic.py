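"""Synthetic inputs with the statistical structure the screen assumes.

The default scenario emulates a desk-scale AGO-CLASH experiment:
3 control + 3 knockout chimera libraries, ~50 miRNAs, ~200 transcripts,
5 planted TDMD trigger sites, 10 decoy sites each failing exactly one named
screening criterion, ~100 generic (non-TDMD) miRNA-target interaction sites
carrying the bulk of the hybrid mass, plus non-hybrid background reads.
Reads are 4-nt UMI + [miRNA + target fragment, either order] + 4-nt UMI +
3' adapter, with Poisson PCR duplication and negative-binomial molecule
counts per site and library.

Every planted site is verified at generation time: triggers must classify
as TDMD candidates with an energy margin and clear the abundance filters;
each decoy must verifiably fail its designated criterion.  This makes
end-to-end recovery of the planted truth a well-posed test.

All generators are deterministic given (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .duplex_fold import DEFAULT_MODEL, EnergyModel, fold_duplex
from .io_formats import MiRNA, Transcript
from .quant import CountMatrix
from .repression import revcomp
from .screen import DEFAULT_CONFIG, ScreenConfig, classify_tdmd

_BASES = "ACGU"
_BYTE_LUT = np.frombuffer(b"ACGU", dtype=np.uint8)

# partner that CANNOT pair with the given base (for seed mismatches)
_NONPAIR = {"A": "A", "C": "C", "G": "A", "U": "C"}
# weakest admissible partner: wobble where the base allows it
_WEAK_PAIR = {"A": "U", "C": "G", "G": "U", "U": "G"}
_WC_PARTNER = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _random_rna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[b] for b in rng.integers(0, 4, n))


def gen_mirnome(n: int, seed: int) -> list[MiRNA]:
    """``n`` random mature miRNAs (21-23 nt, unique ids and 18-nt prefixes)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    mirnas: list[MiRNA] = []
    prefixes: set[str] = set()
    while len(mirnas) < n:
        length = int(rng.choice([21, 22, 23]))
        seq = _random_rna(rng, length)
        if seq[:18] in prefixes:
            continue
        prefixes.add(seq[:18])
        mirnas.append(MiRNA(f"mir-{len(mirnas) + 1:03d}", seq, "guide"))
    return mirnas


def gen_transcriptome(
    n: int,
    seed: int,
    length_range: tuple[int, int] = (400, 900),
    utr_start_frac: tuple[float, float] = (0.40, 0.60),
) -> list[Transcript]:
    """``n`` random transcripts with a 3'UTR annotation."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    out = []
    for i in range(n):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        frac = rng.uniform(*utr_start_frac)
        out.append(
            Transcript(
                f"tx-{i + 1:04d}", f"gene-{i + 1:04d}", _random_rna(rng, length),
                cds_end=int(length * frac),
            )
        )
    return out


# ---------------------------------------------------------------------------
# site construction


@dataclass(frozen=True)
class TriggerSpec:
    """Recipe for a planted duplex site.

    ``kind`` selects the construction: 'trigger' (TDMD-compatible),
    'decoy_seed', 'decoy_seed_only', 'decoy_perfect', 'decoy_loop7',
    'decoy_energy', 'decoy_low_abundance', 'decoy_no_enrichment'.
    ``loop_len``/``loop_strand`` shape the central loop; ``three_prime_mode``
    is 'full_window' (last 8 all paired) or 'nine_run' (>=9-pair run touching
    the window); ``n_gu`` wobble pairs are substituted into the 3' helix.
    """

    kind: str = "trigger"
    loop_len: int = 4
    loop_strand: str = "target"  # 'mirna' | 'target'
    three_prime_mode: str = "full_window"
    n_gu: int = 0


class PlantingError(ValueError):
    """Raised when a spec cannot be satisfied for a given miRNA."""


def _with_gu(block: str, mirna_part: str, n_gu: int) -> str:
    """Substitute up to n_gu wobble partners into a reverse-complement block.

    ``block`` is revcomp(mirna_part); block index i faces mirna_part
    position len-1-i.  Interior positions with G/U miRNA bases are eligible.
    """
    if n_gu <= 0:
        return block
    chars = list(block)
    L = len(mirna_part)
    done = 0
    for i in range(1, len(chars) - 1):  # keep helix ends Watson-Crick
        base = mirna_part[L - 1 - i]
        if base in "GU":
            chars[i] = _WEAK_PAIR[base]
            done += 1
            if done == n_gu:
                break
    return "".join(chars)


def build_site_sequence(
    mirna_seq: str, spec: TriggerSpec, rng: np.random.Generator
) -> str:
    """The target-site sequence (5'->3') implementing ``spec`` against the
    miRNA.  Raises PlantingError when the spec is geometrically unsatisfiable
    for this miRNA length."""
    m = mirna_seq
    L = len(m)
    kind = spec.kind
    if kind == "decoy_seed_only":
        return revcomp(m[:8])
    if kind == "decoy_perfect":
        return revcomp(m)
    if kind == "decoy_loop7":
        return revcomp(m[8:]) + _random_rna(rng, 7) + revcomp(m[:8])
    if kind == "decoy_seed":
        site = revcomp(m[8:]) + _random_rna(rng, spec.loop_len) + revcomp(m[:8])
        # break pairing at miRNA positions 4 and 5 (inside the seed)
        chars = list(site)
        off = len(site) - 8  # start of the seed-facing block
        for pos in (4, 5):  # 1-based miRNA position p faces block index 8-p
            chars[off + 8 - pos] = _NONPAIR[m[pos - 1]]
        return "".join(chars)
    if kind == "decoy_energy":
        # seed 2-8 + full last-8 window, all-wobble-where-possible partners;
        # the miRNA-side gap between the helices is the central loop
        gap = L - 16
        if not 1 <= gap <= 6:
            raise PlantingError(f"decoy_energy needs miRNA length 17-22, got {L}")
        block3 = "".join(_WEAK_PAIR[b] for b in reversed(m[L - 8 :]))
        block_seed = "".join(_WEAK_PAIR[b] for b in reversed(m[1:8]))
        return block3 + block_seed
    # TDMD-compatible geometries (triggers and the two abundance decoys)
    l = spec.loop_len
    if spec.three_prime_mode == "nine_run":
        l = L - 18
        if not 1 <= l <= 6:
            raise PlantingError(f"nine_run needs miRNA length 19-24, got {L}")
        # pair 1..8 and a 9-run at positions L-9..L-1 (touches the window)
        block3 = revcomp(m[L - 10 : L - 1])
        return _with_gu(block3, m[L - 10 : L - 1], spec.n_gu) + revcomp(m[:8])
    if not 1 <= l <= 6:
        raise PlantingError("central loop length must be 1-6")
    if spec.loop_strand == "mirna":
        if 9 + l > L - 7:
            raise PlantingError(f"miRNA-side loop {l} too long for length {L}")
        block3 = revcomp(m[8 + l :])
        return _with_gu(block3, m[8 + l :], spec.n_gu) + revcomp(m[:8])
    block3 = revcomp(m[8:])
    return (
        _with_gu(block3, m[8:], spec.n_gu)
        + _random_rna(rng, l)
        + revcomp(m[:8])
    )


_NAMED_CRITERION = {
    "decoy_seed": "seed",
    "decoy_seed_only": "three_prime",
    "decoy_perfect": "central",
    "decoy_loop7": "central",
    "decoy_energy": "energy",
    "decoy_low_abundance": "abundance",
    "decoy_no_enrichment": "enrichment",
}

DG_MARGIN = 2.0  # planted triggers must fold below dg_max - margin


def _verify_site(
    mirna: MiRNA,
    window: str,
    spec: TriggerSpec,
    screen_config: ScreenConfig,
    model: EnergyModel,
) -> str | None:
    """Classify the planted window; return a failure reason or None if the
    spec's contract holds (candidate-with-margin for TDMD-compatible
    geometries, named-criterion failure for structural decoys)."""
    call = classify_tdmd(fold_duplex(mirna.sequence, window, model), screen_config)
    structural = spec.kind in (
        "trigger", "decoy_low_abundance", "decoy_no_enrichment",
    )
    if structural:
        if not call.is_candidate:
            failed = [
                name
                for name, ok in [
                    ("seed", call.seed_ok),
                    ("three_prime", call.three_prime_ok),
                    ("central", call.central_ok),
                    ("energy", call.energy_ok),
                ]
                if not ok
            ]
            return f"not a candidate (failed: {', '.join(failed)})"
        if call.dg > screen_config.dg_max - DG_MARGIN:
            return f"dg {call.dg} above margin {screen_config.dg_max - DG_MARGIN}"
        return None
    if call.is_candidate:
        return "decoy classifies as candidate"
    named = _NAMED_CRITERION[spec.kind]
    ok_flags = {
        "seed": call.seed_ok,
        "three_prime": call.three_prime_ok,
        "central": call.central_ok,
        "energy": call.energy_ok,
    }
    if ok_flags[named]:
        return f"decoy does not fail its named criterion {named!r}"
    return None


def plant_trigger(
    transcript: Transcript,
    mirna: MiRNA,
    spec: TriggerSpec,
    offset: int | None = None,
    rng: np.random.Generator | None = None,
    screen_config: ScreenConfig = DEFAULT_CONFIG,
    model: EnergyModel = DEFAULT_MODEL,
) -> tuple[Transcript, tuple[int, int]]:
    """Insert a site implementing ``spec`` into the transcript's 3'UTR.

    ``offset`` positions the site within the UTR (random when None).  The
    planted window — site plus the downstream context the pipeline will see
    after 3' extension — is folded and classified; a PlantingError lists the
    violated contract if the construction does not behave as specified.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    if transcript.cds_end is None:
        raise PlantingError(f"transcript {transcript.id} has no UTR annotation")
    site = build_site_sequence(mirna.sequence, spec, rng)
    utr_len = len(transcript.sequence) - transcript.cds_end
    slack = 45  # room for downstream extension context
    if utr_len < slack + 20:
        raise PlantingError(f"3'UTR of {transcript.id} too short")
    if offset is None:
        offset = int(rng.integers(10, utr_len - slack))
    pos = transcript.cds_end + offset
    new_seq = transcript.sequence[:pos] + site + transcript.sequence[pos:]
    new_t = replace(transcript, sequence=new_seq)
    interval = (pos, pos + len(site))
    # verify on the windows the screen can see (max/min fragment jitter)
    ext = screen_config.extension
    for a, b in ((pos, pos + len(site) + ext), (max(0, pos - 4), pos + len(site) + ext)):
        reason = _verify_site(mirna, new_seq[a:b], spec, screen_config, model)
        if reason is not None:
            raise PlantingError(f"{spec.kind} for {mirna.id}: {reason}")
    return new_t, interval


# ---------------------------------------------------------------------------
# scenario


@dataclass(frozen=True)
class PlantedSite:
    kind: str  # 'trigger' or a decoy kind
    mirna_id: str
    transcript_id: str
    site_start: int
    site_end: int
    control_mean: float  # molecules per control library
    enrichment: float  # KO mean multiplier
    spec: TriggerSpec
    failed_criterion: str | None  # None for true triggers

    @property
    def is_trigger(self) -> bool:
        return self.kind == "trigger"


@dataclass(frozen=True)
class GenericSite:
    """A non-TDMD interaction site (hybrid background)."""

    mirna_id: str
    transcript_id: str
    start: int
    end: int
    mean: float


@dataclass
class SimTruth:
    """Ground truth of one simulated scenario."""

    triggers: list[PlantedSite]
    decoys: list[PlantedSite]
    mirna_fold_changes: dict[str, float]
    target_shift: float
    seed: int

    @property
    def trigger_keys(self) -> set[tuple[str, str]]:
        return {(t.mirna_id, t.transcript_id) for t in self.triggers}

    @property
    def decoy_keys(self) -> set[tuple[str, str]]:
        return {(d.mirna_id, d.transcript_id) for d in self.decoys}


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic scenario (defaults = the full default scenario)."""

    n_mirnas: int = 50
    n_transcripts: int = 200
    n_triggers: int = 5
    n_libraries: int = 3  # per condition
    reads_per_library: int = 200_000  # raw reads (pre-collapse), approximate
    background_fraction: float = 0.6  # non-hybrid molecules
    nb_dispersion: float = 0.2  # CLASH site counts, var = m + a*m^2
    pcr_lambda: float = 0.5  # copies = 1 + Poisson(lambda)
    trigger_enrichment: float = 8.0
    trigger_control_mean: float = 40.0
    low_abundance_control_mean: float = 0.6
    no_enrichment_control_mean: float = 100.0
    n_generic_sites: int = 100
    generic_log_mean: float = math.log(300.0)
    generic_log_sigma: float = 0.8
    n_background_fragments: int = 300
    adapter3: str = "AGATCGGAAGAGCACACGTCTG"
    umi_len: int = 4
    fragment_jitter5: int = 4  # max extra nt upstream of the site
    fragment_trim3: int = 8  # max nt trimmed from the fragment 3' end
    n_fragment_variants: int = 4
    verify_recoverable: bool = True  # redraw counts that defeat the plant
    target_shift: float = 0.3  # mRNA repression, log2 units
    mirna_fold: float = 8.0  # trigger-miRNA elevation in small-RNA libraries


_DEFAULT_TRIGGER_SPECS = [
    TriggerSpec("trigger", loop_len=3, loop_strand="mirna"),
    TriggerSpec("trigger", loop_len=4, loop_strand="target", n_gu=1),
    TriggerSpec("trigger", loop_len=2, loop_strand="mirna", n_gu=1),
    TriggerSpec("trigger", three_prime_mode="nine_run"),
    TriggerSpec("trigger", loop_len=6, loop_strand="target", n_gu=2),
]

_DEFAULT_DECOY_SPECS = [
    TriggerSpec("decoy_seed", loop_len=4),
    TriggerSpec("decoy_seed", loop_len=3),
    TriggerSpec("decoy_seed_only"),
    TriggerSpec("decoy_seed_only"),
    TriggerSpec("decoy_perfect"),
    TriggerSpec("decoy_loop7"),
    TriggerSpec("decoy_energy"),
    TriggerSpec("decoy_energy"),
    TriggerSpec("decoy_low_abundance", loop_len=4),
    TriggerSpec("decoy_no_enrichment", loop_len=3),
]


@dataclass
class Scenario:
    config: SimConfig
    mirnas: list[MiRNA]
    transcripts: list[Transcript]
    truth: SimTruth
    generic_sites: list[GenericSite]
    screen_config: ScreenConfig

    @property
    def planted(self) -> list[PlantedSite]:
        return self.truth.triggers + self.truth.decoys


def build_scenario(
    config: SimConfig = SimConfig(),
    seed: int = 0,
    screen_config: ScreenConfig = DEFAULT_CONFIG,
    model: EnergyModel = DEFAULT_MODEL,
) -> Scenario:
    """Generate the mirnome/transcriptome and plant all sites, retrying
    miRNA assignments until every generation-time contract is satisfied."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    mirnas = gen_mirnome(config.n_mirnas, seed)
    transcripts = gen_transcriptome(config.n_transcripts, seed)

    specs = _DEFAULT_TRIGGER_SPECS[: config.n_triggers] + _DEFAULT_DECOY_SPECS
    if config.n_triggers > len(_DEFAULT_TRIGGER_SPECS):
        extra = config.n_triggers - len(_DEFAULT_TRIGGER_SPECS)
        specs = (
            _DEFAULT_TRIGGER_SPECS
            + [
                TriggerSpec("trigger", loop_len=1 + i % 6, loop_strand="target")
                for i in range(extra)
            ]
            + _DEFAULT_DECOY_SPECS
        )

    available = list(range(len(mirnas)))
    tx_order = list(rng.permutation(config.n_transcripts))
    planted: list[PlantedSite] = []
    new_transcripts = {t.id: t for t in transcripts}
    used_tx: set[str] = set()
    for spec in specs:
        tx_idx = next(i for i in tx_order if transcripts[i].id not in used_tx)
        base_t = new_transcripts[transcripts[tx_idx].id]
        last_err: Exception | None = None
        for k, mi in enumerate(list(available)):
            try:
                t2, (a, b) = plant_trigger(
                    base_t, mirnas[mi], spec, rng=rng,
                    screen_config=screen_config, model=model,
                )
            except PlantingError as exc:
                last_err = exc
                continue
            available.remove(mi)
            used_tx.add(base_t.id)
            new_transcripts[t2.id] = t2
            if spec.kind == "decoy_low_abundance":
                mean, enrich = config.low_abundance_control_mean, config.trigger_enrichment
            elif spec.kind == "decoy_no_enrichment":
                mean, enrich = config.no_enrichment_control_mean, 1.0
            else:
                mean, enrich = config.trigger_control_mean, config.trigger_enrichment
            planted.append(
                PlantedSite(
                    spec.kind, mirnas[mi].id, t2.id, a, b, mean, enrich, spec,
                    _NAMED_CRITERION.get(spec.kind),
                )
            )
            break
        else:
            raise PlantingError(
                f"could not satisfy spec {spec} with any miRNA: {last_err}"
            )

    transcripts = [new_transcripts[t.id] for t in transcripts]
    tx_by_id = {t.id: t for t in transcripts}

    # generic interaction sites on unplanted transcripts
    free_tx = [t for t in transcripts if t.id not in used_tx]
    generic: list[GenericSite] = []
    for _ in range(config.n_generic_sites):
        t = free_tx[int(rng.integers(len(free_tx)))]
        m = mirnas[int(rng.integers(len(mirnas)))]
        start = int(rng.integers(0, len(t.sequence) - 35))
        mean = float(np.exp(rng.normal(config.generic_log_mean, config.generic_log_sigma)))
        generic.append(GenericSite(m.id, t.id, start, start + 30, mean))

    triggers = [p for p in planted if p.is_trigger]
    decoys = [p for p in planted if not p.is_trigger]
    truth = SimTruth(
        triggers,
        decoys,
        {t.mirna_id: config.mirna_fold for t in triggers},
        config.target_shift,
        seed,
    )
    return Scenario(config, mirnas, transcripts, truth, generic, screen_config)


# ---------------------------------------------------------------------------
# CLASH read simulation


def _nb_draw(rng: np.random.Generator, mean: float, alpha: float, size: int):
    """NB with var = mean + alpha * mean^2 (DESeq-style dispersion)."""
    if mean <= 0:
        return np.zeros(size, dtype=np.int64)
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mean), size)


def _umi_strings(rng: np.random.Generator, n: int, umi_len: int) -> list[str]:
    if n == 0:
        return []
    flat = _BYTE_LUT[rng.integers(0, 4, size=n * 2 * umi_len, dtype=np.int64)]
    s = flat.tobytes().decode("ascii")
    w = 2 * umi_len
    return [s[i * w : (i + 1) * w] for i in range(n)]


def _emit(
    out: list[str],
    insert: str,
    n_mol: int,
    rng: np.random.Generator,
    adapter: str,
    lam: float,
    umi_len: int,
) -> None:
    """Append n_mol molecules (with PCR duplicates) of one insert template."""
    if n_mol <= 0:
        return
    umis = _umi_strings(rng, n_mol, umi_len)
    copies = 1 + rng.poisson(lam, n_mol)
    for u, c in zip(umis, copies):
        read = u[:umi_len] + insert + u[umi_len:] + adapter
        if c == 1:
            out.append(read)
        else:
            out.extend([read] * int(c))


def _planned_condition_totals(scenario: Scenario) -> dict[str, float]:
    """Expected clean molecules per condition (RPM denominator estimate)."""
    cfg = scenario.config
    m_planned = cfg.reads_per_library / (1.0 + cfg.pcr_lambda)
    bg = round(cfg.background_fraction * m_planned)
    generic_sum = sum(g.mean for g in scenario.generic_sites)
    totals = {}
    for cond in ("control", "ko"):
        planted_sum = sum(
            p.control_mean * (p.enrichment if cond == "ko" else 1.0)
            for p in scenario.planted
        )
        totals[cond] = cfg.n_libraries * (bg + generic_sum + planted_sum)
    return totals


def _draw_planted_counts(
    scenario: Scenario, rng: np.random.Generator
) -> dict[tuple[str, str], np.ndarray]:
    """Per-site count matrix (2 x n_libraries: control row, ko row).

    With ``verify_recoverable`` the draw is repeated until the realized
    abundance respects the site's role: triggers and structural decoys clear
    both screen filters with a 10% guard; the low-abundance / no-enrichment
    decoys fail their designated filter with the same guard.
    """
    cfg = scenario.config
    sc = scenario.screen_config
    totals = _planned_condition_totals(scenario)
    out = {}
    for site in scenario.planted:
        for attempt in range(1000):
            ctrl = _nb_draw(rng, site.control_mean, cfg.nb_dispersion, cfg.n_libraries)
            ko = _nb_draw(
                rng, site.control_mean * site.enrichment, cfg.nb_dispersion,
                cfg.n_libraries,
            )
            if not cfg.verify_recoverable:
                break
            ko_rpm = 1e6 * ko.sum() / totals["ko"]
            ctrl_rpm = 1e6 * ctrl.sum() / totals["control"]
            fold = (ko_rpm + sc.rpm_pseudocount) / (ctrl_rpm + sc.rpm_pseudocount)
            if site.kind == "decoy_low_abundance":
                if ko_rpm < 0.9 * sc.rpm_min:
                    break
            elif site.kind == "decoy_no_enrichment":
                if ko_rpm > 1.1 * sc.rpm_min and fold < 0.9 * sc.fold_min:
                    break
            elif ko_rpm > 1.1 * sc.rpm_min and fold > 1.1 * sc.fold_min:
                break
        else:
            raise PlantingError(f"could not draw recoverable counts for {site.kind}")
        out[(site.mirna_id, site.transcript_id)] = np.vstack([ctrl, ko])
    return out


def sim_clash_reads(
    scenario: Scenario, seed: int | None = None
) -> tuple[dict[str, list[str]], dict[str, str]]:
    """Raw CLASH reads per library.

    Returns (library_id -> raw read sequences, library_id -> condition).
    Library ids are control_1..n and ko_1..n.  Byte-identical for a given
    (scenario, seed); ``seed`` defaults to the scenario's own seed.
    """
    cfg = scenario.config
    seed = scenario.truth.seed if seed is None else seed
    root = np.random.SeedSequence([seed, 404])
    rng_global = np.random.default_rng(root.spawn(1)[0])

    mirna_by_id = {m.id: m for m in scenario.mirnas}
    tx_by_id = {t.id: t for t in scenario.transcripts}

    planted_counts = _draw_planted_counts(scenario, rng_global)

    # fixed per-site fragment variants: (extra 5' nt, 3' trim)
    def variants_for(site_len: int) -> list[tuple[int, int]]:
        vs = [(0, 0)]
        while len(vs) < cfg.n_fragment_variants:
            vs.append(
                (
                    int(rng_global.integers(0, cfg.fragment_jitter5 + 1)),
                    int(rng_global.integers(0, cfg.fragment_trim3 + 1)),
                )
            )
        return vs

    planted_variants = {
        (p.mirna_id, p.transcript_id): variants_for(p.site_end - p.site_start)
        for p in scenario.planted
    }
    generic_variants = [variants_for(g.end - g.start) for g in scenario.generic_sites]

    # non-hybrid background templates and weights
    m_planned = cfg.reads_per_library / (1.0 + cfg.pcr_lambda)
    bg_n = int(round(cfg.background_fraction * m_planned))
    mirna_w = np.exp(rng_global.normal(0.0, 1.0, len(scenario.mirnas)))
    mirna_w /= mirna_w.sum()
    frag_templates = []
    for _ in range(cfg.n_background_fragments):
        t = scenario.transcripts[int(rng_global.integers(len(scenario.transcripts)))]
        flen = int(rng_global.integers(30, 51))
        start = int(rng_global.integers(0, max(1, len(t.sequence) - flen)))
        frag_templates.append(t.sequence[start : start + flen])
    frag_w = np.exp(rng_global.normal(0.0, 1.0, len(frag_templates)))
    frag_w /= frag_w.sum()

    libraries: dict[str, list[str]] = {}
    conditions: dict[str, str] = {}
    lib_seeds = root.spawn(2 * cfg.n_libraries)
    li = 0
    for cond_i, cond in enumerate(("control", "ko")):
        for rep in range(cfg.n_libraries):
            lib_id = f"{cond}_{rep + 1}"
            conditions[lib_id] = cond
            rng = np.random.default_rng(lib_seeds[li])
            li += 1
            reads: list[str] = []

            def emit_site(mid, tid, start, end, count, variants):
                if count <= 0:
                    return
                m_seq = mirna_by_id[mid].sequence
                t_seq = tx_by_id[tid].sequence
                n_var = len(variants)
                split = rng.multinomial(count, [1.0 / n_var] * n_var)
                for (j5, trim), n_v in zip(variants, split):
                    if n_v == 0:
                        continue
                    frag = t_seq[max(0, start - j5) : max(start + 12, end - trim)]
                    n_first = int(rng.binomial(n_v, 0.5))
                    _emit(reads, m_seq + frag, n_first, rng, cfg.adapter3,
                          cfg.pcr_lambda, cfg.umi_len)
                    _emit(reads, frag + m_seq, n_v - n_first, rng, cfg.adapter3,
                          cfg.pcr_lambda, cfg.umi_len)

            for p in scenario.planted:
                n = int(planted_counts[(p.mirna_id, p.transcript_id)][cond_i, rep])
                emit_site(
                    p.mirna_id, p.transcript_id, p.site_start, p.site_end, n,
                    planted_variants[(p.mirna_id, p.transcript_id)],
                )
            for g, vs in zip(scenario.generic_sites, generic_variants):
                n = int(_nb_draw(rng, g.mean, cfg.nb_dispersion, 1)[0])
                emit_site(g.mirna_id, g.transcript_id, g.start, g.end, n, vs)

            n_mirna_bg = bg_n // 2
            for m, n in zip(scenario.mirnas, rng.multinomial(n_mirna_bg, mirna_w)):
                _emit(reads, m.sequence, int(n), rng, cfg.adapter3,
                      cfg.pcr_lambda, cfg.umi_len)
            for frag, n in zip(
                frag_templates, rng.multinomial(bg_n - n_mirna_bg, frag_w)
            ):
                _emit(reads, frag, int(n), rng, cfg.adapter3,
                      cfg.pcr_lambda, cfg.umi_len)
            libraries[lib_id] = reads
    return libraries, conditions


# ---------------------------------------------------------------------------
# small-RNA reads (3' tailing/trimming phenotype)


def sim_smallrna_reads(
    mirnas: list[MiRNA],
    trigger_mirna_ids: set[str],
    condition: str,
    seed: int,
    mirna_fold: float = 8.0,
    base_mean: float = 300.0,
    dispersion: float = 0.01,
    p_mod_control: float = 0.15,
    p_mod_ko: float = 0.05,
    adapter3: str = "AGATCGGAAGAGCACACGTCTG",
    umi_len: int = 4,
) -> list[str]:
    """One small-RNA library: raw reads with UMIs, adapters and 3'-end
    modification (1-3 nt extension or trimming).

    Trigger miRNAs are modified at ``p_mod_control`` in the control
    condition and ``p_mod_ko`` after trigger knockout (TDMD engagement
    exposes the miRNA 3' end); their abundance is multiplied by
    ``mirna_fold`` in the KO.  Other miRNAs use ``p_mod_ko`` throughout.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 505]))
    reads: list[str] = []
    for m in mirnas:
        is_trigger = m.id in trigger_mirna_ids
        mean = base_mean * np.exp(rng.normal(0, 0.5))
        if is_trigger and condition == "ko":
            mean *= mirna_fold
        n = int(_nb_draw(rng, mean, dispersion, 1)[0])
        p_mod = (
            (p_mod_control if condition == "control" else p_mod_ko)
            if is_trigger
            else p_mod_ko
        )
        mods = rng.random(n) < p_mod
        for k in range(n):
            seq = m.sequence
            if mods[k]:
                delta = int(rng.integers(1, 4))
                if rng.random() < 0.5:
                    seq = seq + _random_rna(rng, delta)
                else:
                    seq = seq[: max(18, len(seq) - delta)]
            _emit(reads, seq, 1, rng, adapter3, 0.0, umi_len)
    return reads


# ---------------------------------------------------------------------------
# count matrices


def sim_mirna_count_matrix(
    mirna_ids: list[str],
    fold_changes: dict[str, float],
    seed: int,
    n_per_condition: int = 3,
    dispersion: float = 0.01,
    mean_log_range: tuple[float, float] = (math.log(1000), math.log(5000)),
) -> CountMatrix:
    """Negative-binomial miRNA count matrix (3+3 samples) with planted
    KO elevation of the miRNAs in ``fold_changes``."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 606]))
    means = np.exp(rng.uniform(*mean_log_range, len(mirna_ids)))
    cols = {}
    condition_of = {}
    for cond in ("control", "ko"):
        for rep in range(n_per_condition):
            sample = f"{cond}_{rep + 1}"
            condition_of[sample] = cond
            col = np.empty(len(mirna_ids), dtype=np.int64)
            for i, mid in enumerate(mirna_ids):
                mean = means[i]
                if cond == "ko":
                    mean *= fold_changes.get(mid, 1.0)
                col[i] = _nb_draw(rng, mean, dispersion, 1)[0]
            cols[sample] = col
    df = pd.DataFrame(cols, index=list(mirna_ids))
    return CountMatrix(df, condition_of)


def sim_mrna_counts(
    genes: list[str],
    target_ids: set[str],
    delta: float,
    seed: int,
    n_per_condition: int = 3,
    dispersion: float = 0.1,
    mean_log_range: tuple[float, float] = (math.log(200), math.log(5000)),
) -> CountMatrix:
    """NB mRNA counts with planted repression: target genes' KO means are
    multiplied by 2**(-delta)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 707]))
    means = np.exp(rng.uniform(*mean_log_range, len(genes)))
    is_target = np.array([g in target_ids for g in genes])
    cols = {}
    condition_of = {}
    for cond in ("control", "ko"):
        for rep in range(n_per_condition):
            sample = f"{cond}_{rep + 1}"
            condition_of[sample] = cond
            m = means.copy()
            if cond == "ko":
                m[is_target] *= 2.0 ** (-delta)
            r = 1.0 / dispersion
            cols[sample] = rng.negative_binomial(r, r / (r + m))
    df = pd.DataFrame(cols, index=list(genes))
    return CountMatrix(df, condition_of)


def sim_cfc_logfc(
    delta: float,
    seed: int,
    n_targets: int = 500,
    n_non_targets: int = 5000,
    sd: float = 0.4,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian per-gene log2 fold changes: targets shifted by -delta."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 808]))
    targets = rng.normal(-delta, sd, n_targets)
    non_targets = rng.normal(0.0, sd, n_non_targets)
    return targets, non_targets
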