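"""End-to-end orchestration: collapse -> diversity -> neutrality ->
mismatch/dating -> network, from one declarative config.

``run_pipeline`` produces, per population group, one molecular-diversity row
and one demographic-expansion row (neutrality statistics, mismatch fit,
expansion date), plus network exports for the whole table — the layout of a
standard mtDNA phylogeography results section.  Every reported number is
computed by the corresponding single-stage function; the pipeline adds no
code paths of its own.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from .hapio import (
    HaplotypeTable,
    expand_table,
    haplotype_alignment,
    read_haplotype_table,
)
from .diversity import diversity_stats
from .neutrality import UndefinedStatisticError, neutrality_pvalues
from .mismatch import (
    DegenerateHistogramError,
    expansion_time,
    fit_sudden_expansion,
    mismatch_histogram,
    tau_bootstrap_ci,
)
from .mjn import build_mjn, network_stats, write_edgelist, write_graphml

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Declarative pipeline configuration.

    ``groups`` maps group name -> set of locality labels (pooled);
    ``length`` is the locus length L for per-site diversity.  Defaults pin
    the analysis conventions: equal site weights and epsilon 0 for the
    network, gamma shape 0.3 for distances, mu = 7.3e-5 per generation,
    generation time 1 year, 1000 bootstrap replicates, seed 42.  The
    mismatch stage operates on distinct haplotypes (one row each); set
    ``mismatch_weighted`` to use individual frequencies instead.
    """

    table_path: str | None = None
    groups: dict[str, frozenset[str]] = field(default_factory=dict)
    length: int = 0
    mu: float = 7.30e-5
    gen_years: float = 1.0
    epsilon: int = 0
    n_sims: int = 1000
    bootstrap_reps: int = 1000
    seed: int = 42
    mismatch_weighted: bool = False
    output_dir: str = "mtexpand_out"

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be > 0")

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        groups = {k: frozenset(v) for k, v in raw.pop("groups", {}).items()}
        return cls(groups=groups, **raw)


def run_pipeline(config: RunConfig, table: HaplotypeTable | None = None) -> dict:
    """Run the full analysis; returns the report dict and writes outputs.

    ``table`` may be passed directly (e.g. a packaged fixture); otherwise
    ``config.table_path`` is read.  Outputs: ``report.json``,
    ``diversity.tsv``, ``expansion.tsv``, ``network.graphml``,
    ``network_edges.tsv`` under ``config.output_dir``.
    """
    if table is None:
        if config.table_path is None:
            raise ValueError("either a table or config.table_path is required")
        table = read_haplotype_table(config.table_path)
    unknown_locs = set().union(*config.groups.values()) - set(table.localities) if config.groups else set()
    if unknown_locs:
        raise ValueError(f"config references unknown localities: {sorted(unknown_locs)}")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "n_haplotypes": table.n_haplotypes,
        "n_individuals": table.n,
        "policies": {
            "S": "gap_as_state",
            "k": "gap_as_missing",
            "mismatch": "haplotype-level" if not config.mismatch_weighted else "weighted",
            "network": {"epsilon": config.epsilon, "weights": "equal", "indel_columns": "removed"},
        },
        "groups": {},
    }
    for name, locs in config.groups.items():
        locs = set(locs)
        try:
            aln = expand_table(table, locs, length=config.length)
        except Exception as exc:
            raise RuntimeError(f"group {name!r}: {exc}") from exc
        grp: dict = {"n": aln.n}
        div = diversity_stats(aln, L=config.length or None)
        grp["diversity"] = asdict(div)
        try:
            neu = neutrality_pvalues(aln, n_sims=config.n_sims, seed=config.seed)
            grp["neutrality"] = asdict(neu)
        except (UndefinedStatisticError, ValueError) as exc:
            logger.warning("group %s: neutrality tests unavailable (%s)", name, exc)
            grp["neutrality"] = None
        mis_aln = (
            aln if config.mismatch_weighted else haplotype_alignment(table, locs, length=config.length)
        )
        try:
            hist = mismatch_histogram(mis_aln)
            fit = fit_sudden_expansion(hist)
            ci = tau_bootstrap_ci(
                mis_aln, B=max(config.bootstrap_reps, 100), level=0.90, seed=config.seed
            )
            t_years, ci_years = expansion_time(
                fit.tau, config.mu, config.gen_years, tau_ci=ci
            )
            grp["expansion"] = {
                "tau": fit.tau,
                "theta0": fit.theta0,
                "theta1": fit.theta1,
                "ssd": fit.ssd,
                "raggedness": fit.r,
                "mu": config.mu,
                "gen_years": config.gen_years,
                "t_years": t_years,
                "tau_ci_90": ci,
                "t_years_ci_90": ci_years,
                "mismatch_counts": list(hist.counts),
            }
        except (DegenerateHistogramError, ValueError) as exc:
            logger.warning("group %s: mismatch stage unavailable (%s)", name, exc)
            grp["expansion"] = None
        report["groups"][name] = grp
    net = build_mjn(table, epsilon=config.epsilon)
    report["network"] = {
        k: v for k, v in network_stats(net).items() if k != "degrees"
    } | {"degrees": dict(network_stats(net)["degrees"])}
    write_graphml(net, out / "network.graphml")
    write_edgelist(net, out / "network_edges.tsv")
    _write_diversity_tsv(report, out / "diversity.tsv")
    _write_expansion_tsv(report, out / "expansion.tsv")
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _write_diversity_tsv(report: dict, path) -> None:
    cols = ["group", "n", "S", "n_hap", "h", "sd_h", "pi", "sd_pi", "k"]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(cols) + "\n")
        for name, grp in report["groups"].items():
            d = grp["diversity"]
            fh.write(
                "\t".join(
                    [name]
                    + [str(d[c]) if not isinstance(d[c], float) else f"{d[c]:.4f}" for c in cols[1:]]
                )
                + "\n"
            )


def _write_expansion_tsv(report: dict, path) -> None:
    cols = ["group", "D", "p_D", "Fs", "p_Fs", "raggedness", "tau", "t_years", "t_ci_low", "t_ci_high"]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(cols) + "\n")
        for name, grp in report["groups"].items():
            neu, exp = grp["neutrality"], grp["expansion"]
            row = [name]
            row += (
                [f"{neu['D']:.3f}", f"{neu['p_D']:.3f}", f"{neu['Fs']:.3f}", f"{neu['p_Fs']:.3f}"]
                if neu
                else ["NA"] * 4
            )
            if exp:
                lo, hi = exp["t_years_ci_90"] or ("NA", "NA")
                row += [f"{exp['raggedness']:.3f}", f"{exp['tau']:.3f}", str(exp["t_years"]), str(lo), str(hi)]
            else:
                row += ["NA"] * 5
            fh.write("\t".join(row) + "\n")
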