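"""End-to-end analysis and simulation pipelines (file in, files out).

These functions tie the modules together the way the command-line interface
exposes them: read a contact stream, partition it into days, run the
multiscale-entropy analysis per day, and summarize; or run the simulator
and emit tij/metadata/series files plus a summary.  All outputs are plain
UTF-8 text tables.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np

from . import entropy, netmodel, network_series, noise
from .io_contacts import (CommunityMap, ContactEventList, partition_days,
                          read_communities, read_tij, write_communities,
                          write_tij)

log = logging.getLogger(__name__)

__all__ = ["analyze", "simulate", "make_fixture", "parse_model_config",
           "write_model_config"]


def analyze(contacts_path, metadata_path=None, steps_per_day: int = 2000,
            tau_max: int = 100, out_dir=".", taus=None) -> dict:
    """Full MSE analysis of a tij contact file.

    Writes per-day and day-averaged entropy curves for {K(t)} and {W(t)},
    a per-day (H, M) table, degree and weight distributions of the daily
    aggregated networks, and — when community metadata is given — the
    per-day modularity Q and mixing-ratio estimate p_hat.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    events = read_tij(contacts_path)
    communities = read_communities(metadata_path) if metadata_path else None
    days = partition_days(events, steps_per_day)

    summary: dict = {"n_days": len(days), "n_events": events.n_events}
    curves_K, curves_W = [], []
    stats_rows = []
    all_degrees, all_weights = [], []
    q_values, p_values = [], []
    for d, day in enumerate(days, start=1):
        if not day.events:
            continue
        series = network_series.extract_series(day, T=steps_per_day)
        for name, x, bucket in (("K", series.K_t, curves_K),
                                ("W", series.W_t, curves_W)):
            curve = entropy.mse_curve(x, tau_max=tau_max, taus=taus)
            bucket.append(curve)
            _write(out / f"day{d:02d}_mse_{name}.tsv", _curve_table(curve))
            try:
                st = entropy.series_stats(x)
                stats_rows.append((f"day{d:02d}_{name}", st.H, st.M))
            except ValueError:
                stats_rows.append((f"day{d:02d}_{name}", np.nan, np.nan))
        agg = network_series.aggregate(day)
        all_degrees.extend(agg.degrees())
        all_weights.extend(agg.weights())
        if communities is not None:
            q_values.append(network_series.modularity(agg, communities))
            try:
                p_values.append(network_series.estimate_mixing_ratio(agg, communities))
            except (ValueError, network_series.UndefinedValueError):
                pass

    for name, bucket in (("K", curves_K), ("W", curves_W)):
        if bucket:
            avg = entropy.average_curves(bucket)
            _write(out / f"mse_{name}_mean.tsv", avg.to_table())
            summary[f"mse_{name}_mean"] = avg
    _write(out / "series_stats.tsv",
           "series\tH\tM\n" + "".join(f"{n}\t{h:.8g}\t{m:.8g}\n"
                                      for n, h, m in stats_rows))
    if all_degrees:
        _write(out / "degree_dist.tsv",
               network_series.distribution(all_degrees, "linear", 20).to_table())
    if all_weights:
        _write(out / "weight_dist.tsv",
               network_series.distribution(all_weights, "logarithmic", 20).to_table())
    if communities is not None and q_values:
        summary["Q_mean"] = float(np.mean(q_values))
        lines = [f"Q_mean\t{np.mean(q_values):.8g}"]
        if p_values:
            summary["p_hat_mean"] = float(np.mean(p_values))
            lines.append(f"p_hat_mean\t{np.mean(p_values):.8g}")
        _write(out / "community_stats.tsv", "\n".join(lines) + "\n")
    summary["stats"] = stats_rows
    return summary


def simulate(config: netmodel.ModelConfig, seed: int, replicates: int = 1,
             out_dir=".", taus=None, tau_max: int = 100) -> dict:
    """Run the temporal-network simulator and write one bundle per replicate.

    Emits ``sim_<r>.tij`` (and a shared community metadata file when the
    configuration plants communities) plus a per-replicate series table,
    and a summary with replicate-averaged entropy curves for {K(t)} and
    {W(t)}, degree/weight distributions, and the mean planted-partition Q.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    curves_K, curves_W = [], []
    degrees, weights, q_values = [], [], []
    communities = None
    if config.n_communities > 1:
        labels = config.community_labels()
        communities = CommunityMap({str(i): str(labels[i]) for i in range(config.N)})
        write_communities(communities, out / "communities.txt")
    for r in range(replicates):
        cfg = dataclasses.replace(config, seed=[int(seed), r])
        net = netmodel.generate_network(cfg)
        write_tij(net.events, out / f"sim_{r:03d}.tij")
        _write(out / f"sim_{r:03d}_series.tsv", net.series.to_table())
        curves_K.append(entropy.mse_curve(net.series.K_t, tau_max=tau_max, taus=taus))
        curves_W.append(entropy.mse_curve(net.series.W_t, tau_max=tau_max, taus=taus))
        agg = network_series.aggregate(net.events)
        degrees.extend(agg.degrees())
        weights.extend(agg.weights())
        if communities is not None:
            str_map = CommunityMap({i: communities.assignment[str(i)]
                                    for i in range(config.N)})
            q_values.append(network_series.modularity(agg, str_map))
    summary: dict = {"replicates": replicates}
    for name, bucket in (("K", curves_K), ("W", curves_W)):
        avg = entropy.average_curves(bucket)
        _write(out / f"mse_{name}_mean.tsv", avg.to_table())
        summary[f"mse_{name}_mean"] = avg
    _write(out / "degree_dist.tsv",
           network_series.distribution(degrees, "linear", 20).to_table())
    _write(out / "weight_dist.tsv",
           network_series.distribution(weights, "logarithmic", 20).to_table())
    if q_values:
        summary["Q_mean"] = float(np.mean(q_values))
        _write(out / "community_stats.tsv", f"Q_mean\t{np.mean(q_values):.8g}\n")
    return summary


_CASES = {
    # (t_h, ratio_K, ratio_L): the three environmental regimes
    "case1": dict(t_h=200, ratio_K=3.0, ratio_L=1.0),
    "case2": dict(t_h=100, ratio_K=3.0, ratio_L=1.0),
    "case3": dict(t_h=100, ratio_K=9.0, ratio_L=1.5),
}


def make_fixture(kind: str, seed: int = 0, out_dir=".", days: int = 2) -> list[Path]:
    """Small deterministic datasets for tests and examples.

    Kinds: ``case1|case2|case3`` (multi-day tij file from the simulator),
    ``community`` (planted 5-community variants across p in {0, 0.2, 0.5, 1}),
    ``null`` (plain activity-driven run), ``noise`` (three reference series).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if kind in _CASES:
        config = netmodel.ModelConfig(seed=seed, **_CASES[kind])
        records = []
        for d in range(days):
            cfg = dataclasses.replace(config, seed=[int(seed), d])
            net = netmodel.generate_network(cfg)
            offset = d * config.T
            records.extend((t + offset, i, j) for t, i, j in net.events)
        path = out / f"{kind}.tij"
        write_tij(ContactEventList.from_records(records), path)
        written.append(path)
    elif kind == "community":
        for r, p in enumerate((0.0, 0.2, 0.5, 1.0)):
            config = netmodel.ModelConfig(n_communities=5, p=p,
                                          seed=[int(seed), r], **_CASES["case2"])
            net = netmodel.generate_network(config)
            path = out / f"community_p{p:g}.tij"
            write_tij(net.events, path)
            written.append(path)
        labels = config.community_labels()
        meta = out / "communities.txt"
        write_communities(
            CommunityMap({str(i): str(labels[i]) for i in range(config.N)}), meta)
        written.append(meta)
    elif kind == "null":
        acts = netmodel.sample_activities(("powerlaw", 2.5, 1e-3), 1000,
                                          np.random.default_rng(seed))
        net = netmodel.generate_null_network(acts, T=500, seed=seed + 1)
        path = out / "null.tij"
        write_tij(net.events, path)
        written.append(path)
    elif kind == "noise":
        T = 30_000
        for name, series in (("white", noise.white_noise(T, seed)),
                             ("pink", noise.pink_noise(T, seed=seed + 1)),
                             ("brown", noise.brown_noise(T, seed + 2))):
            path = out / f"noise_{name}.txt"
            np.savetxt(path, series, fmt="%.8g")
            written.append(path)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return written


_MODEL_FIELDS = {f.name: f.type for f in dataclasses.fields(netmodel.ModelConfig)}


def parse_model_config(path) -> netmodel.ModelConfig:
    """Parse a key-value text config (one ``key value`` pair per line)."""
    kwargs: dict = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace("=", " ").split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'key value'")
            key, value = parts
            if key not in _MODEL_FIELDS:
                raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
            if key in ("activity", "activation"):
                kwargs[key] = value
            elif key in ("N", "K", "W", "T", "n", "t_h", "n_communities", "seed"):
                kwargs[key] = int(value)
            else:
                kwargs[key] = float(value)
    return netmodel.ModelConfig(**kwargs)


def write_model_config(config: netmodel.ModelConfig, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for f in dataclasses.fields(config):
            value = getattr(config, f.name)
            if value is not None:
                fh.write(f"{f.name} {value}\n")


def _curve_table(curve: entropy.EntropyCurve) -> str:
    lines = ["tau\tS_E"]
    for t, v in zip(curve.tau, curve.S_E):
        lines.append(f"{t}\t{v:.8g}")
    return "\n".join(lines) + "\n"


def _write(path: Path, text: str) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(text)
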