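"""End-to-end orchestration of the trigger screen:
preprocess -> hybrid calling -> duplex folding -> structural classification
-> abundance filters -> reports.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .duplex_fold import DEFAULT_MODEL, EnergyModel, fold_duplex
from .hybrid_caller import (
    HybridSiteSummary,
    aggregate_hybrids,
    build_kmer_index,
    call_hybrids,
)
from .io_formats import (
    FragmentHit,
    HybRecordLine,
    parse_fastq,
    read_mirna_fasta,
    read_transcript_fasta,
    write_hyb,
)
from .preprocess import preprocess_reads
from .screen import DEFAULT_CONFIG, ScreenConfig, TriggerCall, classify_tdmd, screen_triggers


@dataclass
class RunReport:
    """Machine-readable account of one screen run."""

    stage_counts: dict = field(default_factory=dict)
    high_confidence: list = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    elapsed: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class ScreenResult:
    triggers: list[TriggerCall]
    summaries: list[HybridSiteSummary]
    duplex_map: dict
    report: RunReport

    @property
    def high_confidence(self) -> list[TriggerCall]:
        return [t for t in self.triggers if t.high_confidence]


def screen_libraries(
    raw_reads_by_library: dict[str, list[str]],
    conditions: dict[str, str],
    mirnas,
    transcripts,
    adapter3: str,
    config: ScreenConfig = DEFAULT_CONFIG,
    model: EnergyModel = DEFAULT_MODEL,
) -> ScreenResult:
    """Run the full screen on in-memory raw reads (one list per library)."""
    report = RunReport(thresholds=asdict(config))
    t0 = time.perf_counter()
    clean_by_lib = {}
    clean_totals = {}
    for lib, raw in raw_reads_by_library.items():
        clean, prep = preprocess_reads(
            raw, adapter3, umi_len=config.umi_len, min_length=config.min_read_len
        )
        clean_by_lib[lib] = clean
        clean_totals[lib] = len(clean)
        report.stage_counts[f"preprocess/{lib}"] = prep.as_dict()
    report.elapsed["preprocess"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    index = build_kmer_index(list(transcripts))
    records = []
    hybrid_totals = {}
    split_cache: dict = {}  # shared across libraries (same references)
    for lib, clean in clean_by_lib.items():
        recs, stats = call_hybrids(
            clean, list(mirnas), index, lib, config, _split_cache=split_cache
        )
        records.extend(recs)
        hybrid_totals[lib] = stats["hybrid"]
        report.stage_counts[f"hybrid_calling/{lib}"] = stats
    report.elapsed["hybrid_calling"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    summaries = aggregate_hybrids(
        records, conditions, clean_totals, config, hybrid_totals
    )
    report.stage_counts["sites"] = len(summaries)
    report.elapsed["aggregate"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    mirna_by_id = {m.id: m for m in mirnas}
    tx_by_id = {t.id: t for t in transcripts}
    duplex_map = {}
    calls = {}
    for s in summaries:
        site_seq = tx_by_id[s.transcript_id].sequence[s.site_start : s.site_end]
        duplex = fold_duplex(mirna_by_id[s.mirna_id].sequence, site_seq, model)
        key = (s.mirna_id, s.transcript_id, s.site_start, s.site_end)
        duplex_map[key] = duplex
        calls[key] = classify_tdmd(duplex, config)
    report.elapsed["fold_classify"] = round(time.perf_counter() - t0, 3)

    triggers = screen_triggers(summaries, calls, config)
    hc = [t for t in triggers if t.high_confidence]
    report.stage_counts["candidates"] = sum(1 for t in triggers if t.call.is_candidate)
    report.stage_counts["high_confidence"] = len(hc)
    report.high_confidence = [
        {
            "mirna": t.mirna_id,
            "transcript": t.transcript_id,
            "site": [t.site_start, t.site_end],
            "ko_rpm": round(t.ko_rpm, 2),
            "fold_change": round(t.fold_change, 2),
            "dg": t.call.dg,
        }
        for t in hc
    ]
    return ScreenResult(triggers, summaries, duplex_map, report)


def run_simulated_screen(sim_config=None, seed: int = 0, config: ScreenConfig = DEFAULT_CONFIG):
    """Simulate the default scenario and screen it; returns (result, truth)."""
    from .synthetic import SimConfig, build_scenario, sim_clash_reads

    # the scenario is always generated (and its plants verified) against the
    # default screening thresholds; `config` governs only the screening stage
    sim_config = sim_config or SimConfig()
    scenario = build_scenario(sim_config, seed)
    libraries, conditions = sim_clash_reads(scenario)
    result = screen_libraries(
        libraries, conditions, scenario.mirnas, scenario.transcripts,
        sim_config.adapter3, config,
    )
    result.report.seeds["scenario"] = seed
    return result, scenario.truth


def triggers_to_frame(triggers: list[TriggerCall], duplex_map: dict | None = None) -> pd.DataFrame:
    rows = []
    for t in triggers:
        key = (t.mirna_id, t.transcript_id, t.site_start, t.site_end)
        pairing = duplex_map[key].render() if duplex_map else ""
        rows.append(
            {
                "mirna": t.mirna_id,
                "transcript": t.transcript_id,
                "site_start": t.site_start,
                "site_end": t.site_end,
                "pairing": pairing,
                "dg": t.call.dg,
                "central_loop": t.call.central_loop_len,
                "seed_ok": t.call.seed_ok,
                "three_prime_ok": t.call.three_prime_ok,
                "central_ok": t.call.central_ok,
                "energy_ok": t.call.energy_ok,
                "is_candidate": t.call.is_candidate,
                "ko_rpm": t.ko_rpm,
                "control_rpm": t.control_rpm,
                "fold_change": t.fold_change,
                "high_confidence": t.high_confidence,
            }
        )
    return pd.DataFrame(rows)


def summaries_to_hyb(
    summaries: list[HybridSiteSummary], duplex_map: dict, mirnas, transcripts
) -> list[HybRecordLine]:
    """One representative hyb-dialect record per merged site."""
    mirna_by_id = {m.id: m for m in mirnas}
    tx_by_id = {t.id: t for t in transcripts}
    out = []
    for s in summaries:
        key = (s.mirna_id, s.transcript_id, s.site_start, s.site_end)
        m_seq = mirna_by_id[s.mirna_id].sequence
        site_seq = tx_by_id[s.transcript_id].sequence[s.site_start : s.site_end]
        total = sum(s.counts.values())
        out.append(
            HybRecordLine(
                read_id=f"{s.mirna_id}_{s.transcript_id}_{s.site_start}",
                read_sequence=m_seq + site_seq,
                dg=duplex_map[key].dg,
                frag1=FragmentHit(s.mirna_id, 0, len(m_seq), 0, len(m_seq), total),
                frag2=FragmentHit(
                    s.transcript_id,
                    len(m_seq),
                    len(m_seq) + len(site_seq),
                    s.site_start,
                    s.site_end,
                    total,
                ),
            )
        )
    return out


def run_screen(config_path: str | Path) -> ScreenResult:
    """File-driven screen: a YAML config names the inputs, thresholds and
    output directory; writes candidates.tsv, hybrids.hyb and report.json."""
    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    missing = [
        p
        for p in [cfg["mirnas"], cfg["transcripts"]]
        + [lib["fastq"] for lib in cfg["libraries"]]
        if not Path(p).exists()
    ]
    if missing:
        raise FileNotFoundError(f"missing inputs: {missing}")
    screen_config = (
        ScreenConfig(**{k: tuple(v) if k == "seed_span" else v for k, v in cfg.get("thresholds", {}).items()})
        if cfg.get("thresholds")
        else DEFAULT_CONFIG
    )
    mirnas = read_mirna_fasta(cfg["mirnas"])
    transcripts = read_transcript_fasta(cfg["transcripts"])
    raw = {
        lib["id"]: [seq for _, seq, _ in parse_fastq(lib["fastq"])]
        for lib in cfg["libraries"]
    }
    conditions = {lib["id"]: lib["condition"] for lib in cfg["libraries"]}
    result = screen_libraries(
        raw, conditions, mirnas, transcripts, cfg.get("adapter3", ""), screen_config
    )
    out_dir = Path(cfg.get("out_dir", "."))
    out_dir.mkdir(parents=True, exist_ok=True)
    triggers_to_frame(result.triggers, result.duplex_map).to_csv(
        out_dir / "candidates.tsv", sep="\t", index=False
    )
    write_hyb(
        summaries_to_hyb(result.summaries, result.duplex_map, mirnas, transcripts),
        out_dir / "hybrids.hyb",
    )
    (out_dir / "report.json").write_text(result.report.to_json())
    return result
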