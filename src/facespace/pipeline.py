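"""Full study protocol: condition runs, parameter sweeps, statistics,
figures.

A *condition* is a train:test property pair on one dataset (e.g. ID:SE =
train the Fisher subspace on identity, evaluate sex after relabeling).
The protocol runs, per dataset, every condition over a grid of PCA
component counts and face-sample counts, applies the omission rule
(rows with fewer face samples than components are marked omitted),
aggregates percent-correct DMS scores, compares conditions with pooled
t-tests, and emits distance summaries / KS tests and figures at a fixed
figure scale.

Per grid point the steps are: stratified subsample over the training
property -> PCA on the subsample -> Fisher fit on the train half ->
orthogonal padding to a common dimensionality across the dataset's
conditions -> projection of the held-out half -> relabel to the test
property -> DMS score + distance summary.
"""
from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .faces import (
    EXPRESSION_LEVELS,
    AttributeSpec,
    FaceRenderer,
    LabeledFaceSet,
    make_identity_bank,
    render_expression_dataset,
    render_invariant_dataset,
)
from .stats import StatResult, class_distance_summary, compare_conditions_ttest
from .subspace import fit_lfd, fit_pca, pad_orthogonal, project_fisher, project_pca
from .transfer import dms_performance, relabel

__all__ = [
    "ConditionSpec",
    "SweepConfig",
    "DEFAULT_CONFIG",
    "default_config",
    "build_datasets",
    "run_condition",
    "run_sweep",
    "run_paper_protocol",
    "make_figures",
    "expected_n_discriminants",
    "distance_histogram",
]

logger = logging.getLogger(__name__)

PROPERTY_SHORT = {"identity": "ID", "sex": "SE", "race": "RA", "expression": "EX"}

RESULTS_COLUMNS = [
    "dataset",
    "train_property",
    "test_property",
    "n_components",
    "n_faces",
    "seed",
    "mode",
    "n_trials",
    "percent_correct",
    "n_discriminants",
    "total_dim",
    "ks_D",
    "ks_p",
    "omitted",
    "omit_reason",
]

MIN_PER_CLASS = 4  # >= 2 train + >= 2 test per retained class


@dataclass(frozen=True)
class ConditionSpec:
    """One train:test condition at one grid point."""

    train_property: str
    test_property: str
    dataset_id: str
    n_pca_components: int
    n_faces: int
    train_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for p in (self.train_property, self.test_property):
            if p not in PROPERTY_SHORT:
                raise ValueError(f"unknown property {p!r}")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")

    @property
    def name(self) -> str:
        return f"{PROPERTY_SHORT[self.train_property]}:{PROPERTY_SHORT[self.test_property]}"


@dataclass(frozen=True)
class SweepConfig:
    """Grids and condition templates for a sweep."""

    conditions: tuple[tuple[str, str, str], ...]  # (train, test, dataset_id)
    components_grid: tuple[int, ...] = tuple(range(6, 43, 2))
    faces_grid: dict = field(
        default_factory=lambda: {
            "invariant": tuple(range(20, 121, 10)),
            "expression": tuple(range(20, 161, 10)),
        }
    )
    base_seed: int = 0
    dms_max_trials: int = 100_000

    def __post_init__(self):
        if list(self.components_grid) != sorted(set(self.components_grid)):
            raise ValueError("components_grid must be strictly increasing")
        for ds, grid in self.faces_grid.items():
            if list(grid) != sorted(set(grid)):
                raise ValueError(f"faces_grid[{ds!r}] must be strictly increasing")


# -- stratified subsampling -------------------------------------------------


def _plan_counts(class_sizes: np.ndarray, n_faces: int) -> np.ndarray:
    """Per-class sample counts for a stratified subsample of ``n_faces``
    over classes with the given sizes: as many classes as possible with
    at least MIN_PER_CLASS each, filled evenly."""
    avail = int(class_sizes.min())
    n_classes = len(class_sizes)
    if n_faces < 2 * MIN_PER_CLASS:
        raise ValueError(f"n_faces={n_faces} too small for 2 stratified classes")
    k_cls = min(n_classes, n_faces // MIN_PER_CLASS)
    base = n_faces // k_cls
    if base > avail:
        k_cls = math.ceil(n_faces / avail)
        if k_cls > n_classes:
            raise ValueError(
                f"cannot draw {n_faces} faces from {n_classes} classes of "
                f"size {avail}"
            )
        base = n_faces // k_cls
    if base < MIN_PER_CLASS:
        raise ValueError(
            f"subsample plan leaves {base} < {MIN_PER_CLASS} samples per class"
        )
    counts = np.full(k_cls, base)
    counts[: n_faces - base * k_cls] += 1
    return counts


def _choose_classes(
    labels: pd.DataFrame, train_property: str, n_classes: int, rng
) -> np.ndarray:
    """Choose which training classes enter the subsample.  Identity
    classes are drawn round-robin over the joint cells of the other
    invariant attributes (sex x race), mirroring the balanced composition
    of the emulated collections; few-class properties are shuffled
    directly."""
    if train_property != "identity":
        classes = labels[train_property].unique()
        return rng.permutation(np.asarray(sorted(classes)))[:n_classes]
    per_id = labels.drop_duplicates("identity").sort_values("identity")
    cells: dict[tuple, list] = {}
    for _, row in per_id.iterrows():
        cells.setdefault((row["sex"], row["race"]), []).append(row["identity"])
    pools = [rng.permutation(np.asarray(v)) for v in cells.values()]
    order = rng.permutation(len(pools))
    chosen: list = []
    i = 0
    while len(chosen) < n_classes:
        pool = pools[order[i % len(pools)]]
        j = i // len(pools)
        if j < len(pool):
            chosen.append(pool[j])
        i += 1
    return np.asarray(chosen[:n_classes])


def expected_n_discriminants(
    faceset: LabeledFaceSet, train_property: str, n_faces: int, n_components: int
) -> int:
    """Discriminant count min(C - 1, k) the subsampling plan will yield;
    used to choose a common padded dimensionality across conditions."""
    sizes = faceset.labels.groupby(train_property).size().to_numpy()
    counts = _plan_counts(sizes, n_faces)
    return min(len(counts) - 1, n_components)


# -- single condition -------------------------------------------------------


def _omitted_row(spec: ConditionSpec, reason: str) -> dict:
    return {
        "dataset": spec.dataset_id,
        "train_property": spec.train_property,
        "test_property": spec.test_property,
        "n_components": spec.n_pca_components,
        "n_faces": spec.n_faces,
        "seed": spec.seed,
        "mode": "",
        "n_trials": 0,
        "percent_correct": np.nan,
        "n_discriminants": 0,
        "total_dim": 0,
        "ks_D": np.nan,
        "ks_p": np.nan,
        "omitted": True,
        "omit_reason": reason,
    }


def run_condition(
    spec: ConditionSpec,
    faceset: LabeledFaceSet,
    target_dim: int | None = None,
    dms_max_trials: int = 100_000,
    return_projection: bool = False,
):
    """Run one train:test condition at one grid point.

    Returns a result-row dict (``omitted=True`` rows for grid points the
    omission rule or the PCA rank bound excludes), and optionally the
    evaluated ProjectedSet and DistanceSummary.
    """
    k, f = spec.n_pca_components, spec.n_faces
    if f < k:
        row = _omitted_row(spec, "n_faces < n_components")
        return (row, None, None) if return_projection else row
    if k > f - 1:  # equality point: PCA rank at most n - 1
        row = _omitted_row(spec, "pca_rank")
        return (row, None, None) if return_projection else row
    if f > faceset.n_samples:
        raise ValueError(
            f"n_faces={f} exceeds dataset size {faceset.n_samples}"
        )

    rng = np.random.default_rng(spec.seed)
    labels = faceset.labels
    sizes = labels.groupby(spec.train_property).size()
    counts = _plan_counts(sizes.to_numpy(), f)
    classes = _choose_classes(labels, spec.train_property, len(counts), rng)

    train_idx, test_idx = [], []
    for cls, cnt in zip(classes, counts):
        pool = np.flatnonzero(labels[spec.train_property].to_numpy() == cls)
        pick = rng.choice(pool, size=cnt, replace=False)
        n_train = cnt - int(cnt * (1.0 - spec.train_fraction))
        n_train = max(2, min(cnt - 2, n_train))
        train_idx.extend(pick[:n_train])
        test_idx.extend(pick[n_train:])
    train_idx = np.asarray(train_idx)
    test_idx = np.asarray(test_idx)

    sub = faceset.take(np.concatenate([train_idx, test_idx]))
    n_train_total = len(train_idx)
    # within-class scatter needs >= k degrees of freedom in the training
    # half, else the discriminant metric is ridge-dominated
    if n_train_total - len(counts) < k:
        row = _omitted_row(spec, "s_w rank deficit")
        return (row, None, None) if return_projection else row
    pca = fit_pca(sub, k)
    coords = project_pca(pca, sub)
    coords_train, coords_test = coords[:n_train_total], coords[n_train_total:]
    labels_train = sub.labels.iloc[:n_train_total]
    labels_test = sub.labels.iloc[n_train_total:].reset_index(drop=True)

    fisher_raw = fit_lfd(
        coords_train,
        labels_train[spec.train_property].to_numpy(),
        trained_property=spec.train_property,
    )
    if target_dim is not None:
        fisher = pad_orthogonal(
            fisher_raw, min(target_dim, k), seed=int(rng.integers(2**31))
        )
    else:
        fisher = fisher_raw
    pset = project_fisher(
        fisher, coords_test, eval_labels=labels_test[spec.train_property].to_numpy()
    )
    # distance summaries / component scatters describe the condition's own
    # discriminant space; padding only equalizes dimensionality for the
    # cross-condition performance comparison
    pset_disc = project_fisher(
        fisher_raw, coords_test,
        eval_labels=labels_test[spec.train_property].to_numpy(),
    )
    try:
        pset = relabel(pset, labels_test, spec.test_property)
        pset_disc = relabel(pset_disc, labels_test, spec.test_property)
        perf = dms_performance(
            pset, mode="auto", max_trials=dms_max_trials,
            seed=int(rng.integers(2**31)),
        )
    except ValueError as exc:
        logger.warning("condition %s at (k=%d, f=%d) degenerate: %s",
                       spec.name, k, f, exc)
        row = _omitted_row(spec, f"degenerate evaluation: {exc}")
        return (row, None, None) if return_projection else row
    try:
        summary = class_distance_summary(pset_disc)
        ks_d, ks_p = summary.ks_D, summary.ks_p
    except ValueError:
        summary, ks_d, ks_p = None, np.nan, np.nan

    row = {
        "dataset": spec.dataset_id,
        "train_property": spec.train_property,
        "test_property": spec.test_property,
        "n_components": k,
        "n_faces": f,
        "seed": spec.seed,
        "mode": perf.mode,
        "n_trials": perf.n_trials,
        "percent_correct": perf.percent_correct,
        "n_discriminants": fisher.n_discriminants,
        "total_dim": fisher.total_dim,
        "ks_D": ks_d,
        "ks_p": ks_p,
        "omitted": False,
        "omit_reason": "",
    }
    return (row, pset_disc, summary) if return_projection else row


# -- sweep ------------------------------------------------------------------


def _row_seed(base_seed: int, dataset_id: str, ci: int, k: int, f: int) -> int:
    ds_code = zlib.crc32(dataset_id.encode()) % (2**31)
    ss = np.random.SeedSequence([base_seed, ds_code, ci, k, f])
    return int(ss.generate_state(1)[0] % (2**31))


def run_sweep(config: SweepConfig, datasets: dict[str, LabeledFaceSet]) -> pd.DataFrame:
    """One result row per condition x grid point.  Within each dataset and
    grid point, all conditions are padded to the maximum discriminant
    count present so Euclidean distances are comparable."""
    rows = []
    by_dataset: dict[str, list[tuple[int, tuple[str, str]]]] = {}
    for ci, (train, test, ds) in enumerate(config.conditions):
        if ds not in datasets:
            raise ValueError(f"condition references unknown dataset {ds!r}")
        by_dataset.setdefault(ds, []).append((ci, (train, test)))

    for ds, conds in by_dataset.items():
        faceset = datasets[ds]
        faces_grid = config.faces_grid[ds]
        for k in config.components_grid:
            for f in faces_grid:
                if f < k or k > f - 1:
                    target = None
                else:
                    target = max(
                        expected_n_discriminants(faceset, train, f, k)
                        for _, (train, _t) in conds
                    )
                for ci, (train, test) in conds:
                    spec = ConditionSpec(
                        train_property=train,
                        test_property=test,
                        dataset_id=ds,
                        n_pca_components=k,
                        n_faces=f,
                        seed=_row_seed(config.base_seed, ds, ci, k, f),
                    )
                    rows.append(
                        run_condition(
                            spec,
                            faceset,
                            target_dim=target,
                            dms_max_trials=config.dms_max_trials,
                        )
                    )
    table = pd.DataFrame(rows, columns=RESULTS_COLUMNS)
    n_omitted = int(table["omitted"].sum())
    logger.info("sweep: %d rows, %d omitted", len(table), n_omitted)
    return table


# -- full protocol ----------------------------------------------------------

INVARIANT_CONDITIONS = (
    ("identity", "identity", "invariant"),
    ("sex", "sex", "invariant"),
    ("race", "race", "invariant"),
    ("identity", "sex", "invariant"),
    ("identity", "race", "invariant"),
)
EXPRESSION_CONDITIONS = (
    ("expression", "expression", "expression"),
    ("identity", "expression", "expression"),
    ("sex", "expression", "expression"),
    ("identity", "identity", "expression"),
    ("expression", "identity", "expression"),
    ("sex", "sex", "expression"),
    ("expression", "sex", "expression"),
)

TTEST_COMPARISONS = (
    # (name, (dataset, train, test) A, (dataset, train, test) B)
    ("ID:ID vs SE:SE (invariant)", ("invariant", "identity", "identity"), ("invariant", "sex", "sex")),
    ("ID:ID vs RA:RA (invariant)", ("invariant", "identity", "identity"), ("invariant", "race", "race")),
    ("SE:SE vs ID:SE (invariant)", ("invariant", "sex", "sex"), ("invariant", "identity", "sex")),
    ("RA:RA vs ID:RA (invariant)", ("invariant", "race", "race"), ("invariant", "identity", "race")),
    ("EX:EX vs ID:EX (expression)", ("expression", "expression", "expression"), ("expression", "identity", "expression")),
    ("EX:EX vs SE:EX (expression)", ("expression", "expression", "expression"), ("expression", "sex", "expression")),
    ("ID:ID vs EX:ID (expression)", ("expression", "identity", "identity"), ("expression", "expression", "identity")),
    ("SE:SE vs EX:SE (expression)", ("expression", "sex", "sex"), ("expression", "expression", "sex")),
)

DEFAULT_CONFIG = {
    "base_seed": 0,
    "outdir": "results",
    "invariant_db": {
        "n_identities": 120,
        "viewpoints": [-10.0, 0.0, 10.0, 20.0, 30.0],
        "noise_sd": 0.02,
        "renderer": {},
    },
    "expression_db": {
        "n_identities": 50,
        "kappa": 0.0,
        "noise_sd": 0.02,
        # photographs with outer features (hairline etc.) carry more
        # identity-specific variance than normalized 3-D renders
        "renderer": {"identity_gain": 1.25},
    },
    "components_grid": list(range(6, 43, 2)),
    "faces_grid_invariant": list(range(20, 121, 10)),
    "faces_grid_expression": list(range(20, 161, 10)),
    "figure_faces": {"invariant": 120, "expression": 160},
    "figure_components": 10,
    "dms_max_trials": 100_000,
    "figures": True,
}


def default_config(overrides: dict | str | Path | None = None) -> dict:
    """The protocol's default configuration, optionally overridden by a
    dict or a YAML file path."""
    return _merged_config(overrides)


def _merged_config(config: dict | str | Path | None) -> dict:
    if config is None:
        config = {}
    elif not isinstance(config, dict):
        config = fio.load_config(config)
    cfg = {**DEFAULT_CONFIG, **config}
    for key in ("invariant_db", "expression_db", "figure_faces"):
        cfg[key] = {**DEFAULT_CONFIG[key], **(config.get(key) or {})}
    return cfg


def _renderer_from(db_cfg: dict, seed: int) -> FaceRenderer:
    return FaceRenderer(seed=seed, **(db_cfg.get("renderer") or {}))


def build_datasets(cfg: dict) -> dict[str, LabeledFaceSet]:
    """Generate the two synthetic collections the protocol runs on."""
    base = int(cfg["base_seed"])
    inv_cfg, exp_cfg = cfg["invariant_db"], cfg["expression_db"]
    inv_spec = AttributeSpec(
        n_identities=int(inv_cfg["n_identities"]),
        viewpoints=tuple(float(v) for v in inv_cfg["viewpoints"]),
    )
    inv_bank = make_identity_bank(inv_spec, seed=base * 4 + 1)
    invariant = render_invariant_dataset(
        inv_bank,
        noise_sd=float(inv_cfg["noise_sd"]),
        seed=base * 4 + 2,
        renderer=_renderer_from(inv_cfg, base * 4 + 2),
    )
    exp_spec = AttributeSpec(
        n_identities=int(exp_cfg["n_identities"]),
        race_levels=("asian",),  # expression collection: all one race
        viewpoints=(0.0,),
    )
    exp_bank = make_identity_bank(exp_spec, seed=base * 4 + 3)
    expression = render_expression_dataset(
        exp_bank,
        kappa=float(exp_cfg["kappa"]),
        noise_sd=float(exp_cfg["noise_sd"]),
        seed=base * 4 + 4,
        renderer=_renderer_from(exp_cfg, base * 4 + 4),
    )
    return {"invariant": invariant, "expression": expression}


def _condition_scores(table: pd.DataFrame, key: tuple[str, str, str]) -> np.ndarray:
    ds, train, test = key
    sel = table[
        (table["dataset"] == ds)
        & (table["train_property"] == train)
        & (table["test_property"] == test)
        & (~table["omitted"])
    ]
    return sel["percent_correct"].to_numpy()


def compute_ttests(table: pd.DataFrame) -> pd.DataFrame:
    """The printed cross-condition pooled t-tests over sweep scores."""
    rows = []
    for name, key_a, key_b in TTEST_COMPARISONS:
        a = _condition_scores(table, key_a)
        b = _condition_scores(table, key_b)
        if len(a) < 2 or len(b) < 2:
            logger.warning("skipping t-test %s: too few runs", name)
            continue
        res: StatResult = compare_conditions_ttest(a, b)
        rows.append({"comparison": name, "t": res.t_value, "df": res.df,
                     "p": res.p_value})
    return pd.DataFrame(rows, columns=["comparison", "t", "df", "p"])


def run_paper_protocol(config: dict | str | Path | None = None) -> dict:
    """Run the full protocol and write results.csv, stats.csv,
    ks_stats.csv, figures/ and run.log under the configured outdir.

    Returns a dict with the results table, t-test table, KS table,
    figure-scale projections and the output directory.
    """
    cfg = _merged_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)

    log_handler = logging.FileHandler(outdir / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root_logger = logging.getLogger("facespace")
    root_logger.addHandler(log_handler)
    root_logger.setLevel(logging.INFO)
    try:
        logger.info("base_seed=%s", cfg["base_seed"])
        datasets = build_datasets(cfg)
        sweep_cfg = SweepConfig(
            conditions=INVARIANT_CONDITIONS + EXPRESSION_CONDITIONS,
            components_grid=tuple(cfg["components_grid"]),
            faces_grid={
                "invariant": tuple(cfg["faces_grid_invariant"]),
                "expression": tuple(cfg["faces_grid_expression"]),
            },
            base_seed=int(cfg["base_seed"]),
            dms_max_trials=int(cfg["dms_max_trials"]),
        )
        results = run_sweep(sweep_cfg, datasets)
        fio.write_results(results, outdir / "results.csv")

        stats = compute_ttests(results)
        fio.write_results(stats, outdir / "stats.csv")

        # figure-scale runs: fixed face counts, default component count
        projections = {}
        ks_rows = []
        k_fig = int(cfg["figure_components"])
        for ds, conds in (
            ("invariant", INVARIANT_CONDITIONS),
            ("expression", EXPRESSION_CONDITIONS),
        ):
            f_fig = int(cfg["figure_faces"][ds])
            target = max(
                expected_n_discriminants(datasets[ds], train, f_fig, k_fig)
                for train, _test, _ds in conds
            )
            for ci, (train, test, _ds) in enumerate(conds):
                spec = ConditionSpec(
                    train_property=train,
                    test_property=test,
                    dataset_id=ds,
                    n_pca_components=k_fig,
                    n_faces=f_fig,
                    seed=_row_seed(int(cfg["base_seed"]) + 1, ds, ci, k_fig, f_fig),
                )
                row, pset, summary = run_condition(
                    spec,
                    datasets[ds],
                    target_dim=target,
                    dms_max_trials=int(cfg["dms_max_trials"]),
                    return_projection=True,
                )
                name = f"{spec.name} ({ds})"
                projections[name] = (pset, summary)
                ks_rows.append(
                    {"condition": name, "ks_D": row["ks_D"], "ks_p": row["ks_p"]}
                )
        ks_table = pd.DataFrame(ks_rows, columns=["condition", "ks_D", "ks_p"])
        fio.write_results(ks_table, outdir / "ks_stats.csv")

        figure_paths = []
        if cfg["figures"]:
            figure_paths = make_figures(results, projections, outdir / "figures")
        n_omitted = int(results["omitted"].sum())
        logger.info("protocol complete: %d rows (%d omitted), %d t-tests",
                    len(results), n_omitted, len(stats))
    finally:
        root_logger.removeHandler(log_handler)
        log_handler.close()
    return {
        "results": results,
        "stats": stats,
        "ks": ks_table,
        "projections": projections,
        "outdir": outdir,
    }


# -- figures ----------------------------------------------------------------


def distance_histogram(summary, bins: int = 20):
    """Shared within/between histogram binning used by the figures.
    Returns (within_counts, between_counts, edges)."""
    both = np.concatenate([summary.within_avg, summary.between_avg])
    edges = np.histogram_bin_edges(both, bins=bins)
    w, _ = np.histogram(summary.within_avg, bins=edges)
    b, _ = np.histogram(summary.between_avg, bins=edges)
    return w, b, edges


def make_figures(results: pd.DataFrame, projections: dict, outdir: str | Path) -> list:
    """Notched per-condition boxplots, 2-D/3-D component scatters and
    within/between distance histograms.  Returns the written paths."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    active = results[~results["omitted"]]
    if len(active) == 0 and not projections:
        raise ValueError("results table is empty; nothing to plot")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []

    for ds in sorted(active["dataset"].unique()):
        sub = active[active["dataset"] == ds]
        conds, data = [], []
        for (train, test), grp in sub.groupby(
            ["train_property", "test_property"], sort=True
        ):
            conds.append(f"{PROPERTY_SHORT[train]}:{PROPERTY_SHORT[test]}")
            data.append(grp["percent_correct"].to_numpy())
        fig, ax = plt.subplots(figsize=(1.2 * len(conds) + 2, 4))
        ax.boxplot(data, notch=True, tick_labels=conds, whis=2.7)
        ax.set_ylabel("percent correct (DMS)")
        ax.set_title(f"{ds} collection")
        ax.axhline(50.0, color="gray", lw=0.8, ls="--")
        path = outdir / f"performance_{ds}.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        paths.append(path)

    for name, (pset, summary) in projections.items():
        if pset is None:
            continue
        safe = name.replace(":", "-").replace(" ", "_").replace("(", "").replace(")", "")
        fig = plt.figure(figsize=(12, 4))
        classes, class_idx = np.unique(pset.eval_labels, return_inverse=True)
        cmap = plt.get_cmap("hsv", len(classes) + 1)
        colors = cmap(class_idx)
        xyz = pset.coordinates
        if xyz.shape[1] < 3:  # low-dim discriminant spaces (e.g. 2 classes)
            xyz = np.hstack([xyz, np.zeros((len(xyz), 3 - xyz.shape[1]))])
        ax3 = fig.add_subplot(1, 3, 1, projection="3d")
        ax3.scatter(xyz[:, 0], xyz[:, 1], xyz[:, 2], c=colors, s=12)
        ax3.set_title(f"{name}: first 3 components")
        ax2 = fig.add_subplot(1, 3, 2)
        ax2.scatter(xyz[:, 0], xyz[:, 1], c=colors, s=12)
        ax2.set_title("first 2 components")
        axh = fig.add_subplot(1, 3, 3)
        if summary is not None:
            w, b, edges = distance_histogram(summary)
            centers = 0.5 * (edges[:-1] + edges[1:])
            width = edges[1] - edges[0]
            axh.bar(centers, w, width=width, alpha=0.6, label="within")
            axh.bar(centers, b, width=width, alpha=0.6, label="between")
            axh.legend()
            axh.set_title(f"D={summary.ks_D:.2f}, p={summary.ks_p:.2g}")
        path = outdir / f"facespace_{safe}.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        paths.append(path)
    return paths
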