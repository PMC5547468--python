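"""Evaluation metrics, privacy-utility sweeps, and the command-line surface.

Accuracy of a perturbed beacon is measured entry-wise over the full
catalogued position set against the raw beacon:

    accuracy = (N_TP + N_TN) / (N_TP + N_TN + N_FP + N_FN)

where a false positive is a "yes" for an entry whose true answer is "no"
and a false negative the reverse. A query-stream variant (accuracy over
an attack's actual query list) is available via ``query_indices``.

The CLI exposes the simulator, the risk table, the cohort attack, the
perturbation mechanisms, single queries (GA4GH-style JSON), and the
accuracy evaluation as subcommands; every stochastic command requires or
generates-and-logs a seed, and all primary outputs are TSV.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import attack as attack_mod
from . import beacon as beacon_mod
from . import privacy as privacy_mod
from . import riskmodel, synthpop

logger = logging.getLogger("beaconrisk")

__all__ = [
    "ConfusionCounts",
    "PrivacyUtilityPoint",
    "confusion_accuracy",
    "recalibrated_profile",
    "privacy_utility_sweep",
    "cli",
    "main",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Entry-wise confusion of a perturbed beacon against the raw one."""

    n_tp: int
    n_tn: int
    n_fp: int
    n_fn: int

    @property
    def total(self) -> int:
        return self.n_tp + self.n_tn + self.n_fp + self.n_fn

    @property
    def accuracy(self) -> float:
        return (self.n_tp + self.n_tn) / self.total if self.total else float("nan")


def confusion_accuracy(
    raw_db: beacon_mod.BeaconDB,
    perturbed_db: beacon_mod.BeaconDB,
    query_indices=None,
) -> ConfusionCounts:
    """Compare presence bits entry-wise over the shared catalog.

    TP: yes kept yes; TN: no kept no; FP: no answered yes; FN: yes
    answered no. ``query_indices`` restricts the comparison to a query
    stream instead of the whole catalog.
    """
    same = (
        raw_db.num_entries == perturbed_db.num_entries
        and np.array_equal(raw_db.catalog_pos, perturbed_db.catalog_pos)
        and (raw_db.catalog_chrom == perturbed_db.catalog_chrom).all()
        and (raw_db.catalog_allele == perturbed_db.catalog_allele).all()
    )
    if not same:
        a = set(zip(raw_db.catalog_chrom, raw_db.catalog_pos, raw_db.catalog_allele))
        b = set(
            zip(
                perturbed_db.catalog_chrom,
                perturbed_db.catalog_pos,
                perturbed_db.catalog_allele,
            )
        )
        raise ValueError(
            "beacons catalog different position sets "
            f"(symmetric difference of {len(a ^ b)} entries)"
        )
    truth = raw_db.present
    answer = perturbed_db.present
    if query_indices is not None:
        idx = np.asarray(query_indices, dtype=np.int64)
        truth, answer = truth[idx], answer[idx]
    return ConfusionCounts(
        n_tp=int((truth & answer).sum()),
        n_tn=int((~truth & ~answer).sum()),
        n_fp=int((~truth & answer).sum()),
        n_fn=int((truth & ~answer).sum()),
    )


def recalibrated_profile(
    profile: riskmodel.RiskProfile, truth_probability: float
) -> riskmodel.RiskProfile:
    """Risk profile recalibrated for a perturbed response distribution.

    If the mechanism answers truthfully with probability t, a yes arrives
    under H0 with probability θ0' = t·θ0 + (1-t)·(1-θ0) and under H1 with
    θ1' = t·θ1 + (1-t)·(1-θ1); the threshold formula is reapplied to θ0'.
    """
    t = float(truth_probability)
    if not 0.0 <= t <= 1.0:
        raise ValueError("truth_probability must lie in [0, 1]")
    theta0 = t * profile.theta0 + (1.0 - t) * (1.0 - profile.theta0)
    theta1 = t * profile.theta1 + (1.0 - t) * (1.0 - profile.theta1)
    d_n = 1.0 - theta0
    sigma0 = float(np.sqrt(d_n * (1.0 - d_n) / profile.n))
    return dataclasses.replace(
        profile,
        D_N=d_n,
        theta0=theta0,
        theta1=theta1,
        sigma0=sigma0,
        t_alpha_prime=int(np.floor(profile.n * (profile.z * sigma0 + theta0))),
        dn_source=f"{profile.dn_source}+recalibrated",
    )


@dataclass(frozen=True)
class PrivacyUtilityPoint:
    """One point of the privacy-utility curve at a fixed query budget."""

    bias: float
    accuracy: float
    power: float
    type1_error: float
    epsilon: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy <= 1.0 or not 0.0 <= self.power <= 1.0:
            raise ValueError("accuracy and power must lie in [0, 1]")


def privacy_utility_sweep(
    db: beacon_mod.BeaconDB,
    panel: synthpop.SNPPanel,
    genotypes: synthpop.GenotypeMatrix,
    case_indices,
    control_indices,
    biases,
    budget: int,
    mechanism: str = "biased_rr",
    delta: float = 1e-3,
    alpha: float = 0.05,
    seed: int | None = None,
    recalibrate: bool = True,
    dn_source: str = "spectrum",
) -> pd.DataFrame:
    """Sweep the mechanism bias, measuring accuracy and attack power.

    For each bias the beacon is perturbed (preprocess semantics),
    whole-catalog accuracy is measured, and the cohort attack is rerun at
    the stated budget — with the decision threshold recalibrated for the
    perturbed response distribution unless ``recalibrate`` is False.
    Returns one row per bias: bias, accuracy, power, type-I error, ε.
    """
    biases = [privacy_mod.normalize_bias(b) for b in biases]
    if not biases:
        raise ValueError("biases must be non-empty")
    base_profile = riskmodel.profile_from_panel(
        panel, db.n_members, delta=delta, alpha=alpha, dn_source=dn_source
    )
    root = np.random.SeedSequence(seed)
    rows = []
    for b, ss in zip(biases, root.spawn(len(biases))):
        perturb_seed, attack_seed = [int(s.generate_state(1)[0] >> 1) for s in ss.spawn(2)]
        try:
            if mechanism == "eliminate_random":
                pdb = privacy_mod.perturb_eliminate_random(db, b, seed=perturb_seed)
            elif mechanism == "biased_rr":
                pdb = privacy_mod.perturb_randomized_response(db, b, seed=perturb_seed)
            else:
                raise ValueError(f"unknown mechanism {mechanism!r}")
            acc = confusion_accuracy(db, pdb).accuracy
            cfg = privacy_mod.PrivacyConfig(mechanism=mechanism, bias=b)
            profile = (
                recalibrated_profile(base_profile, cfg.truth_probability)
                if recalibrate
                else base_profile
            )
            (outcome,) = attack_mod.run_attack_cohort(
                pdb, panel, genotypes, case_indices, control_indices, [budget],
                profile=profile, delta=delta, alpha=alpha, seed=attack_seed,
            )
            eps = privacy_mod.epsilon_of_bias(b).epsilon if mechanism == "biased_rr" \
                else privacy_mod.epsilon_of_bias(1.0 - np.sqrt(1.0 - b)).epsilon
        except ValueError as exc:
            raise ValueError(f"privacy-utility point at bias {b}: {exc}") from exc
        rows.append(
            PrivacyUtilityPoint(
                bias=b,
                accuracy=acc,
                power=outcome.power,
                type1_error=outcome.type1_error,
                epsilon=eps,
            )
        )
    return pd.DataFrame([dataclasses.asdict(p) for p in rows])


# ---------------------------------------------------------------------------
# command-line interface
# ---------------------------------------------------------------------------

def _setup_logging(verbose: bool, quiet: bool) -> None:
    level = logging.DEBUG if verbose else logging.ERROR if quiet else logging.INFO
    logging.basicConfig(
        stream=sys.stderr, level=level, format="%(levelname)s %(name)s: %(message)s",
        force=True,
    )


def _load_config(ctx: click.Context, param, value):
    if value is None:
        return None
    cfg = yaml.safe_load(Path(value).read_text()) or {}
    if not isinstance(cfg, dict):
        raise click.UsageError("config file must map keys to values")
    known = {cmd_name: {p.name for p in cmd.params}
             for cmd_name, cmd in cli.commands.items()}
    default_map: dict = {}
    for key, val in cfg.items():
        if key in cli.commands and isinstance(val, dict):
            bad = set(val) - known[key]
            if bad:
                raise click.UsageError(
                    f"config section {key!r} has unknown keys: {sorted(bad)}"
                )
            default_map[key] = val
        else:
            owners = [c for c, names in known.items() if key in names]
            if not owners:
                raise click.UsageError(f"unknown config key: {key!r}")
            for c in owners:
                default_map.setdefault(c, {})[key] = val
    ctx.default_map = default_map
    return value


def _resolve_seed(seed: int | None) -> int:
    if seed is None:
        seed = int(np.random.SeedSequence().generate_state(1)[0] >> 1)
        logger.info("no --seed given; generated seed %d", seed)
    return int(seed)


@click.group()
@click.option("--verbose", is_flag=True, help="Debug-level logging to stderr.")
@click.option("--quiet", is_flag=True, help="Errors only.")
@click.option(
    "--config", "config", type=click.Path(exists=True), callback=_load_config,
    expose_value=False, is_eager=True,
    help="YAML config file supplying defaults for subcommand options.",
)
def cli(verbose: bool, quiet: bool) -> None:
    """Beacon membership-inference risk: simulate, attack, protect, evaluate."""
    _setup_logging(verbose, quiet)


@cli.command()
@click.option("--num-snps", default=100_000, show_default=True, type=int)
@click.option("--population-size", default=20_000, show_default=True, type=int)
@click.option("--beacon-size", default=1_000, show_default=True, type=int)
@click.option("--extra-individuals", default=400, show_default=True, type=int,
              help="Non-member genotypes to draw (attack controls).")
@click.option("--seed", type=int, default=None)
@click.option("--out-prefix", required=True, type=click.Path())
def simulate(num_snps, population_size, beacon_size, extra_individuals, seed, out_prefix):
    """Generate a panel, genotypes, and a raw beacon table."""
    seed = _resolve_seed(seed)
    root = np.random.SeedSequence(seed)
    s_panel, s_geno = [int(s.generate_state(1)[0] >> 1) for s in root.spawn(2)]
    panel = synthpop.sample_neutral_frequencies(num_snps, population_size, seed=s_panel)
    genotypes = synthpop.sample_genotypes(
        panel, beacon_size + extra_individuals, seed=s_geno
    )
    members = np.arange(beacon_size)
    db = beacon_mod.build_beacon(genotypes, members)
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    synthpop.save_genotypes(genotypes, prefix)
    beacon_mod.write_beacon_table(db, Path(str(prefix) + ".beacon.tsv"))
    Path(str(prefix) + ".members.txt").write_text(
        "\n".join(map(str, members)) + "\n"
    )
    logger.info(
        "simulated %d SNPs, %d genotypes, beacon of %d (seed %d) -> %s.*",
        num_snps, genotypes.num_individuals, beacon_size, seed, prefix,
    )


@cli.command()
@click.option("--n", "n_members", type=int, default=None, help="Beacon member count N.")
@click.option("--a-prime", type=float, default=None)
@click.option("--b-prime", type=float, default=None)
@click.option("--freqs", type=click.Path(exists=True), default=None,
              help="Panel TSV to fit beta parameters from (moment fit).")
@click.option("--label", default="beacon")
@click.option("--delta", default=1e-3, show_default=True, type=float)
@click.option("--alpha", default=0.05, show_default=True, type=float)
@click.option("--paper-z/--exact-z", default=True,
              help="Use the printed z=1.65 at alpha=0.05, or the exact quantile.")
@click.option("--out", type=click.Path(), default=None, help="Output TSV (default stdout).")
def risk(n_members, a_prime, b_prime, freqs, label, delta, alpha, paper_z, out):
    """Closed-form risk report: D_N, query budget n, and threshold t'_alpha."""
    if freqs is not None:
        if n_members is None:
            raise click.UsageError("--n is required with --freqs")
        panel = synthpop.read_panel_tsv(freqs)
        params = riskmodel.fit_beta(panel, method="moments")
        a_prime, b_prime = params.a_prime, params.b_prime
    if n_members is None or a_prime is None or b_prime is None:
        raise click.UsageError("provide either (--n --a-prime --b-prime) or (--n --freqs)")
    df = riskmodel.risk_report(
        [(label, n_members, a_prime, b_prime)],
        delta=delta, alpha=alpha, paper_z=paper_z,
    )
    text = df.to_csv(sep="\t", index=False)
    if out:
        Path(out).write_text(text)
    else:
        click.echo(text, nl=False)


@cli.command("attack")
@click.option("--genotypes", "prefix", required=True, type=click.Path(),
              help="Genotype container prefix from `simulate`.")
@click.option("--beacon", "beacon_path", required=True, type=click.Path(exists=True))
@click.option("--members", "members_path", required=True, type=click.Path(exists=True))
@click.option("--budgets", default="500,1000,2500,5000,10000", show_default=True)
@click.option("--cases", default=100, show_default=True, type=int)
@click.option("--controls", default=100, show_default=True, type=int)
@click.option("--delta", default=1e-3, show_default=True, type=float)
@click.option("--alpha", default=0.05, show_default=True, type=float)
@click.option("--dn-source", default="spectrum", show_default=True,
              type=click.Choice(["spectrum", "beta"]))
@click.option("--kinship", type=float, default=None,
              help="Attack relatives of the cases at this kinship instead.")
@click.option("--seed", type=int, default=None)
@click.option("--out", required=True, type=click.Path())
@click.option("--plot", type=click.Path(), default=None, help="Optional power-curve PNG.")
def attack_cmd(prefix, beacon_path, members_path, budgets, cases, controls,
               delta, alpha, dn_source, kinship, seed, out, plot):
    """Run the cohort membership-inference attack; emit a TSV power curve."""
    seed = _resolve_seed(seed)
    genotypes = synthpop.load_genotypes(prefix)
    db = beacon_mod.read_beacon_table(beacon_path)
    members = np.loadtxt(members_path, dtype=np.int64, ndmin=1)
    non_members = np.setdiff1d(np.arange(genotypes.num_individuals), members)
    if cases > members.size or controls > non_members.size:
        raise click.UsageError("not enough members/non-members for the cohort")
    budget_list = [int(b) for b in str(budgets).split(",") if b.strip()]
    outcomes = attack_mod.run_attack_cohort(
        db, genotypes.panel, genotypes, members[:cases], non_members[:controls],
        budget_list, delta=delta, alpha=alpha, dn_source=dn_source,
        seed=seed, kinship=kinship,
    )
    curve = attack_mod.power_curve(outcomes)
    curve.to_csv(out, sep="\t", index=False)
    logger.info("attack power curve (seed %d) -> %s", seed, out)
    if plot:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots()
        ax.plot(curve["budget"], curve["power"], "o-", label="power")
        ax.plot(curve["budget"], curve["type1_error"], "s--", label="type-I error")
        ax.set_xlabel("queries")
        ax.set_ylabel("rate")
        ax.set_ylim(-0.02, 1.02)
        ax.legend()
        fig.savefig(plot, dpi=120)
        plt.close(fig)


@cli.command()
@click.option("--beacon", "beacon_path", required=True, type=click.Path(exists=True))
@click.option("--mechanism", default="biased_rr", show_default=True,
              type=click.Choice(["eliminate_random", "biased_rr"]))
@click.option("--bias", required=True, type=float,
              help="Truth-retention bias in [0,1], or a percent in (1,100].")
@click.option("--mode", default="preprocess", show_default=True,
              type=click.Choice(["preprocess", "online"]))
@click.option("--deletion-only", is_flag=True,
              help="Mechanism 1 variant that only drops presence bits.")
@click.option("--seed", type=int, default=None)
@click.option("--out", required=True, type=click.Path())
def protect(beacon_path, mechanism, bias, mode, deletion_only, seed, out):
    """Perturb a beacon table with a privacy mechanism."""
    if mode == "online":
        raise click.UsageError(
            "online mode perturbs answers at query time and produces no table; "
            "use the library's answer_online (preprocess is the recommended mode)"
        )
    seed = _resolve_seed(seed)
    db = beacon_mod.read_beacon_table(beacon_path)
    if mechanism == "eliminate_random":
        pdb = privacy_mod.perturb_eliminate_random(
            db, bias, seed=seed, deletion_only=deletion_only
        )
    else:
        pdb = privacy_mod.perturb_randomized_response(db, bias, seed=seed)
    beacon_mod.write_beacon_table(pdb, out)
    logger.info("perturbed beacon (%s, bias %s, seed %d) -> %s",
                mechanism, bias, seed, out)


@cli.command()
@click.option("--beacon", "beacon_path", required=True, type=click.Path(exists=True))
@click.option("--chrom", required=True)
@click.option("--pos", required=True, type=int, help="1-based position.")
@click.option("--allele", default=beacon_mod.ALT, show_default=True)
@click.option("--json", "as_json", is_flag=True, help="GA4GH-style JSON response.")
def query(beacon_path, chrom, pos, allele, as_json):
    """Answer a single beacon query."""
    db = beacon_mod.read_beacon_table(beacon_path)
    exists = beacon_mod.query_beacon(
        db, beacon_mod.BeaconQuery(chrom=chrom, pos=pos - 1, allele=allele)
    )
    click.echo(json.dumps({"exists": bool(exists)}) if as_json else ("yes" if exists else "no"))


@cli.command()
@click.option("--raw", "raw_path", required=True, type=click.Path(exists=True))
@click.option("--perturbed", "pert_path", required=True, type=click.Path(exists=True))
@click.option("--out", type=click.Path(), default=None, help="Output TSV (default stdout).")
def evaluate(raw_path, pert_path, out):
    """Entry-wise confusion counts and accuracy of a perturbed beacon."""
    raw = beacon_mod.read_beacon_table(raw_path)
    pert = beacon_mod.read_beacon_table(pert_path)
    c = confusion_accuracy(raw, pert)
    df = pd.DataFrame(
        [{"n_tp": c.n_tp, "n_tn": c.n_tn, "n_fp": c.n_fp, "n_fn": c.n_fn,
          "accuracy": c.accuracy}]
    )
    text = df.to_csv(sep="\t", index=False)
    if out:
        Path(out).write_text(text)
    else:
        click.echo(text, nl=False)


def main(argv=None) -> int:
    """Entry point returning an exit status (usable programmatically)."""
    try:
        cli.main(args=argv, standalone_mode=False)
    except click.ClickException as exc:
        exc.show()
        return exc.exit_code
    except SystemExit as exc:  # click may still raise for --help
        return int(exc.code or 0)
    return 0
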