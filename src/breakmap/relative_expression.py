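"""Comparative-Ct (delta-delta-Ct) relative quantification.

Implements the standard 2^-ddCt estimator used for qRT-PCR isoform
analysis: each sample's target Ct is normalized against a reference gene
(Pgk1 in the study design this mirrors), group means of the resulting dCt
are compared between a calibrator group (wild type, reported as 1 by
construction) and a test group, and the fold change is 2 to the minus
ddCt.  Amplification efficiency is fixed at 2, the standard assumption;
technical replicates are averaged per (sample, gene) before dCt.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLUMNS = ("sample", "group", "gene", "ct")
MAX_CYCLES = 40.0


class CtTableError(ValueError):
    pass


def validate_ct_table(table: pd.DataFrame, ref_gene: str) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise CtTableError(f"Ct table missing columns: {missing}")
    ct = table["ct"].astype(float)
    if not ((ct > 0) & (ct <= MAX_CYCLES)).all():
        raise CtTableError(f"Ct values must lie in (0, {MAX_CYCLES:g}]")
    have_ref = set(table.loc[table["gene"] == ref_gene, "sample"])
    all_samples = set(table["sample"])
    if all_samples - have_ref:
        raise CtTableError(
            f"reference gene {ref_gene!r} missing in samples: "
            f"{sorted(all_samples - have_ref)}")
    return table


def ddct(table: pd.DataFrame, ref_gene: str,
         calibrator_group: str = "WT",
         test_group: str | None = None) -> pd.DataFrame:
    """Per-gene fold change of the test group relative to the calibrator.

    Returns a frame with columns ``gene``, ``dct_mean_calibrator``,
    ``dct_mean_test``, ``ddct`` and ``fold_change`` (= 2**-ddct).
    """
    table = validate_ct_table(table, ref_gene)
    groups = list(dict.fromkeys(table["group"]))
    if calibrator_group not in groups:
        raise CtTableError(f"no samples in calibrator group {calibrator_group!r}")
    if test_group is None:
        others = [g for g in groups if g != calibrator_group]
        if len(others) != 1:
            raise CtTableError("test_group must be given when groups != 2")
        test_group = others[0]
    if test_group not in groups:
        raise CtTableError(f"no samples in test group {test_group!r}")

    # technical replicates first
    mean_ct = (table.groupby(["group", "sample", "gene"], sort=False)["ct"]
               .mean().reset_index())
    ref = (mean_ct[mean_ct["gene"] == ref_gene]
           .set_index(["group", "sample"])["ct"])
    target = mean_ct[mean_ct["gene"] != ref_gene].copy()
    target["dct"] = (target["ct"].to_numpy()
                     - ref.loc[list(zip(target["group"], target["sample"]))].to_numpy())
    group_means = (target.groupby(["gene", "group"], sort=False)["dct"]
                   .mean().unstack("group"))
    for g in (calibrator_group, test_group):
        if g not in group_means.columns or group_means[g].isna().any():
            raise CtTableError(f"group {g!r} lacks measurements for some genes")
    out = pd.DataFrame({
        "gene": group_means.index,
        "dct_mean_calibrator": group_means[calibrator_group].to_numpy(),
        "dct_mean_test": group_means[test_group].to_numpy(),
    })
    out["ddct"] = out["dct_mean_test"] - out["dct_mean_calibrator"]
    out["fold_change"] = 2.0 ** (-out["ddct"])
    return out.reset_index(drop=True)


def simulate_ct_table(fold_changes: dict[str, float],
                      seed: int,
                      n_per_group: int = 3,
                      noise_sd: float = 0.2,
                      ref_gene: str = "Pgk1",
                      ref_ct: float = 18.0,
                      base_ct: float = 24.0,
                      replicates: int = 1) -> pd.DataFrame:
    """Synthetic Ct table with known true fold changes (mutant vs WT).

    Every well gets independent Gaussian Ct noise; a true fold change f
    shifts the mutant target Ct by -log2(f) relative to WT.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group, n in (("WT", n_per_group), ("mutant", n_per_group)):
        for i in range(n):
            sample = f"{group}{i + 1}"
            for _ in range(replicates):
                rows.append((sample, group, ref_gene,
                             ref_ct + rng.normal(0, noise_sd)))
            for gene, fold in fold_changes.items():
                shift = -np.log2(fold) if group == "mutant" else 0.0
                for _ in range(replicates):
                    rows.append((sample, group, gene,
                                 base_ct + shift + rng.normal(0, noise_sd)))
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))


def fold_interval(true_fold: float, noise_sd: float,
                  n_wt: int, n_mut: int,
                  level: float = 0.95) -> tuple[float, float]:
    """Analytic sampling interval for the 2^-ddCt estimator.

    With per-well Gaussian Ct noise of sd sigma, each sample's dCt has
    variance 2 sigma^2, so ddCt ~ Normal(-log2 f, 2 sigma^2 (1/n1 + 1/n2))
    and the estimator is log2-normal around the true fold.
    """
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * noise_sd * np.sqrt(2.0 * (1.0 / n_wt + 1.0 / n_mut))
    return true_fold * 2.0 ** (-half), true_fold * 2.0 ** half


def write_results(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False)


def read_ct_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
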