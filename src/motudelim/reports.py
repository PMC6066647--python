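"""TSV report writers mirroring the survey's output tables.

Every report starts with a comment header carrying the package version, the
seed and a hash of the run configuration, so that two runs with identical
configuration produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

from . import __version__
from .congruence import MOTUDecision, MotuTally
from .delimit import ConcordanceCounts, ConcordanceLabel, Partition
from .distances import HistogramTable, RankSummary, SpeciesSummary


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header(seed, config: dict) -> str:
    return (
        f"# motudelim v{__version__}\n"
        f"# seed={seed} config={config_hash(config)}\n"
    )


def _fmt(x, nd: int = 2) -> str:
    if x is None:
        return "NA"
    if isinstance(x, float):
        return f"{x:.{nd}f}"
    return str(x)


def write_rank_summaries(
    path: str | Path, summaries: Sequence[RankSummary], seed, config: dict
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header(seed, config))
        fh.write("rank\tn_pairs\tmin_pct\tmean_pct\tmax_pct\n")
        for s in summaries:
            fh.write(
                f"{s.rank}\t{s.n_pairs}\t{_fmt(s.min)}\t{_fmt(s.mean)}\t{_fmt(s.max)}\n"
            )


def write_species_summaries(
    path: str | Path, summaries: Sequence[SpeciesSummary], seed, config: dict
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header(seed, config))
        fh.write(
            "morphospecies\tn_specimens\tmax_intra_pct\tmean_intra_pct\t"
            "nn_species\tnn_distance_pct\tmax_similarity_pct\tbarcode_gap_pct\n"
        )
        for s in summaries:
            fh.write(
                "\t".join(
                    [
                        s.morphospecies,
                        str(s.n_specimens),
                        _fmt(s.max_intra),
                        _fmt(s.mean_intra),
                        s.nn_species,
                        _fmt(s.nn_distance),
                        _fmt(s.max_similarity),
                        _fmt(s.barcode_gap),
                    ]
                )
                + "\n"
            )


def write_histogram(
    path: str | Path, hist: HistogramTable, seed, config: dict
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header(seed, config))
        fh.write(
            f"# rank={hist.rank} below_1pct={hist.fraction_below_1:.4f} "
            f"below_2pct={hist.fraction_below_2:.4f}\n"
        )
        fh.write("bin_low_pct\tbin_high_pct\tcount\n")
        for lo, hi, c in zip(hist.bin_edges[:-1], hist.bin_edges[1:], hist.counts):
            fh.write(f"{lo:.2f}\t{hi:.2f}\t{int(c)}\n")


def write_partitions(
    path: str | Path, partitions: Sequence[Partition], seed, config: dict
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header(seed, config))
        fh.write("specimen_id\tmethod\tcluster_id\n")
        for part in partitions:
            tag = part.method.value
            if "prior" in part.parameters:
                tag += f"[P={part.parameters['prior']:.6g}]"
            for sid in sorted(part.assignment):
                fh.write(f"{sid}\t{tag}\t{part.assignment[sid]}\n")


def write_support(
    path: str | Path, support: dict[str, float], seed, config: dict
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header(seed, config))
        fh.write("specimen_id\tsupport\n")
        for sid in sorted(support):
            fh.write(f"{sid}\t{support[sid]:.4f}\n")


def write_concordance(
    path: str | Path,
    labels: Sequence[ConcordanceLabel],
    counts: ConcordanceCounts,
    seed,
    config: dict,
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header(seed, config))
        fh.write(
            f"# concordant={counts.concordant} discordant={counts.discordant} "
            f"singletons={counts.singleton}\n"
        )
        fh.write("cluster_id\tclassification\tmember_species\n")
        for lab in labels:
            fh.write(
                f"{lab.cluster_id}\t{lab.label.value}\t"
                f"{';'.join(sorted(lab.member_species))}\n"
            )


def write_decisions(
    path: str | Path,
    decisions: Sequence[MOTUDecision],
    tally: MotuTally,
    seed,
    config: dict,
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header(seed, config))
        fh.write(
            f"# species={tally.n_species} cryptic_motus={tally.cryptic_motus} "
            f"new_motu_taxa={tally.new_motu_taxa} "
            f"cryptic_candidates={tally.cryptic_candidates} "
            f"assigned={tally.assigned} suspects={tally.suspects} "
            f"unresolved={tally.unresolved}\n"
        )
        fh.write(
            "morphospecies\tmax_intra_pct\tmean_intra_pct\tn_clades\t"
            "n_bin\tn_abgd\tn_bptp\tverdict\tn_new_motus\tn_cryptic\trationale\n"
        )
        for d in decisions:
            ev = d.evidence
            fh.write(
                "\t".join(
                    [
                        d.morphospecies,
                        _fmt(ev.max_intra),
                        _fmt(ev.mean_intra),
                        _fmt(ev.n_clades),
                        _fmt(ev.n_bin),
                        _fmt(ev.n_abgd),
                        _fmt(ev.n_bptp),
                        d.verdict.value,
                        str(d.n_new_motus),
                        str(d.n_cryptic),
                        d.rationale,
                    ]
                )
                + "\n"
            )


def decisions_to_json(
    decisions: Sequence[MOTUDecision], tally: MotuTally
) -> str:
    payload = {
        "tally": vars(tally),
        "decisions": [
            {
                "morphospecies": d.morphospecies,
                "verdict": d.verdict.value,
                "n_new_motus": d.n_new_motus,
                "n_cryptic": d.n_cryptic,
                "rationale": d.rationale,
                "evidence": {
                    k: (v.value if hasattr(v, "value") else v)
                    for k, v in vars(d.evidence).items()
                },
            }
            for d in decisions
        ],
    }
    return json.dumps(payload, indent=2, sort_keys=True)
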