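"""The TDMD trigger screen: four structural criteria on each miRNA:target
duplex, then two abundance criteria across conditions.

Structural criteria (evaluated on the minimum-energy duplex):

1. seed    — miRNA positions 2-8 all paired (G-U wobbles count);
2. 3' end  — all of the last 8 miRNA positions paired (>7 consecutive pairs
             within the last-8 window), or a run of >= 9 consecutive paired
             positions touching that window;
3. central — the central loop between seed helix and 3' helix is > 0 nt and
             < 7 nt (perfect duplexes are siRNA-like, seed-only structures
             lack the 3' helix; both fail);
4. energy  — duplex dG at or below -16.0 kcal/mol.

High-confidence triggers additionally need knockout-condition hybrid
abundance > 100 RPM and a > 4-fold KO/control enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

from .duplex_fold import DuplexStructure, PairingProfile, pairing_profile


@dataclass(frozen=True)
class ScreenConfig:
    """Every numeric threshold of the screen in one place.

    ``dg_max`` follows the thermodynamic sign convention: a duplex passes
    the energy criterion when its dG is at or below ``dg_max`` (i.e. more
    stable than -16 kcal/mol).
    """

    seed_span: tuple[int, int] = (2, 8)
    last_window: int = 8  # nt at the miRNA 3' end
    full_window_run: int = 8  # ">7 consecutive pairs" inside the window
    long_run: int = 9  # alternative consecutive-pair clause
    long_run_must_touch_window: bool = True
    loop_min: int = 1  # central loop bounds, inclusive
    loop_max: int = 6
    dg_max: float = -16.0  # kcal/mol
    rpm_min: float = 100.0  # KO-condition hybrid abundance (strict >)
    fold_min: float = 4.0  # KO/control enrichment (strict >)
    extension: int = 25  # 3' extension of target fragments, nt
    min_read_len: int = 18
    prefix_len: int = 18  # miRNA prefix used for matching/counting
    umi_len: int = 4
    merge_distance: int = 10  # site-merging window, nt
    rpm_pseudocount: float = 0.1  # RPM added to both conditions for the fold
    rpm_denominator: str = "all_clean_reads"  # or "hybrid_reads"

    def __post_init__(self) -> None:
        if self.loop_min < 1 or self.loop_max >= 7:
            raise ValueError("central loop bounds must satisfy 1 <= min, max < 7")
        if self.rpm_min <= 0 or self.fold_min <= 1:
            raise ValueError("rpm_min must be > 0 and fold_min > 1")

    @classmethod
    def from_yaml(cls, path) -> "ScreenConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "seed_span" in data:
            data["seed_span"] = tuple(data["seed_span"])
        return cls(**data)


DEFAULT_CONFIG = ScreenConfig()


@dataclass(frozen=True)
class TdmdCall:
    """Evaluation of the four structural criteria for one duplex."""

    seed_ok: bool
    three_prime_ok: bool
    central_ok: bool
    energy_ok: bool
    central_loop_len: float  # nt; inf when there is no 3' helix
    dg: float

    @property
    def is_candidate(self) -> bool:
        return self.seed_ok and self.three_prime_ok and self.central_ok and self.energy_ok


@dataclass(frozen=True)
class TriggerCall:
    """One screened miRNA x target site with structure and abundance flags."""

    mirna_id: str
    transcript_id: str
    site_start: int
    site_end: int
    call: TdmdCall
    ko_rpm: float
    control_rpm: float
    fold_change: float
    high_confidence: bool


def check_seed(profile: PairingProfile, config: ScreenConfig = DEFAULT_CONFIG) -> bool:
    """True iff miRNA positions 2-8 are all paired (WC or GU)."""
    lo, hi = config.seed_span
    if profile.mirna_length < hi:
        raise ValueError(f"miRNA shorter than {hi} nt")
    return all(profile.is_paired(p) for p in range(lo, hi + 1))


def check_three_prime(
    profile: PairingProfile, mirna_length: int, config: ScreenConfig = DEFAULT_CONFIG
) -> bool:
    """3' pairing criterion: full last-8 window, or a >= 9-pair run touching it."""
    window_start = mirna_length - config.last_window + 1
    if all(profile.is_paired(p) for p in range(window_start, mirna_length + 1)):
        return True
    # scan maximal runs of consecutive paired positions
    run_start = None
    for p in range(1, mirna_length + 2):
        if p <= mirna_length and profile.is_paired(p):
            if run_start is None:
                run_start = p
        elif run_start is not None:
            run_end = p - 1
            if run_end - run_start + 1 >= config.long_run and (
                not config.long_run_must_touch_window or run_end >= window_start
            ):
                return True
            run_start = None
    return False


def central_loop_len(profile: PairingProfile) -> float:
    """Loop length = max of the miRNA-side and target-side unpaired counts."""
    return max(profile.central_loop)


def check_central(profile: PairingProfile, config: ScreenConfig = DEFAULT_CONFIG) -> bool:
    n = central_loop_len(profile)
    return config.loop_min <= n <= config.loop_max


def classify_tdmd(
    duplex: DuplexStructure, config: ScreenConfig = DEFAULT_CONFIG
) -> TdmdCall:
    """Evaluate all four structural criteria on a folded duplex."""
    profile = pairing_profile(duplex.pairs, duplex.mirna_length)
    loop = central_loop_len(profile)
    return TdmdCall(
        seed_ok=check_seed(profile, config),
        three_prime_ok=check_three_prime(profile, duplex.mirna_length, config),
        central_ok=config.loop_min <= loop <= config.loop_max,
        energy_ok=duplex.dg <= config.dg_max,
        central_loop_len=loop,
        dg=duplex.dg,
    )


def screen_triggers(
    site_summaries,
    duplex_calls: dict,
    config: ScreenConfig = DEFAULT_CONFIG,
) -> list[TriggerCall]:
    """Join per-site abundance summaries with structural calls and apply the
    two high-confidence criteria.

    ``duplex_calls`` maps (mirna_id, transcript_id, site_start, site_end) to
    a TdmdCall.  Output is sorted by KO RPM, descending (ties by ids for
    determinism); all sites are emitted with their flags.
    """
    out: list[TriggerCall] = []
    for s in site_summaries:
        key = (s.mirna_id, s.transcript_id, s.site_start, s.site_end)
        call = duplex_calls[key]
        hc = (
            call.is_candidate
            and s.ko_rpm > config.rpm_min
            and s.fold_change > config.fold_min
        )
        out.append(
            TriggerCall(
                s.mirna_id,
                s.transcript_id,
                s.site_start,
                s.site_end,
                call,
                s.ko_rpm,
                s.control_rpm,
                s.fold_change,
                hc,
            )
        )
    out.sort(key=lambda t: (-t.ko_rpm, t.mirna_id, t.transcript_id, t.site_start))
    return out
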