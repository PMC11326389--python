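"""Synthetic cell-line x protocol benchmark dataset.

The generator emulates a mixture-of-cell-lines design: every line expresses
a disjoint program of genes at elevated level, and every library protocol
scales sequencing depth.  Counts for cell i, gene j are drawn as

    y_ij ~ Poisson( s_i * b_j * e_ij )

with b_j a per-gene baseline (log-normal), s_i a protocol-dependent library
scale with mild per-cell log-normal jitter, and e_ij the line-program
effect: ``program_effect`` fold for the program genes of cell i's line
(modulated per cell by a uniform activity multiplier), 1 elsewhere.  The
activity multiplier gives each program its own cell-to-cell variance axis,
the way real expression programs vary in intensity between cells of the
same line, so the three line signals are full rank rather than pure
group-mean shifts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, CovariateTable, FixtureConfig

__all__ = ["make_fixture_dataset", "FixtureConfig"]


def make_fixture_dataset(config: FixtureConfig) -> tuple[CountMatrix, CovariateTable]:
    """Generate the synthetic benchmark (counts + line/protocol covariates).

    Pure function of ``config.seed``.  Returns a :class:`CountMatrix` of
    ``n_lines * n_protocols * n_cells_per_group`` cells by ``n_genes`` genes
    and a :class:`CovariateTable` with columns ``line`` (categorical),
    ``protocol`` (categorical) and ``library_size`` (log total counts).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_groups = cfg.n_lines * cfg.n_protocols
    n = n_groups * cfg.n_cells_per_group

    line = np.repeat(np.arange(cfg.n_lines), cfg.n_protocols * cfg.n_cells_per_group)
    protocol = np.tile(
        np.repeat(np.arange(cfg.n_protocols), cfg.n_cells_per_group), cfg.n_lines
    )

    baseline = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, cfg.n_genes)
    scale = np.asarray(cfg.libsize_spread, dtype=float)[protocol]
    scale = scale * rng.lognormal(0.0, cfg.cell_log_sd, n)

    # disjoint programs: line l owns genes [l*program_size, (l+1)*program_size)
    effect = np.ones((n, cfg.n_genes))
    if cfg.program_effect > 1:
        # log-normal per-cell program activity: cells of a line express their
        # program at varying intensity, as real expression programs do
        activity = rng.lognormal(0.0, cfg.activity_jitter, n)
        for l in range(cfg.n_lines):
            sel = line == l
            cols = slice(l * cfg.program_size, (l + 1) * cfg.program_size)
            effect[sel, cols] = 1 + (cfg.program_effect - 1) * activity[sel, None]

    mu = scale[:, None] * baseline[None, :] * effect
    counts = rng.poisson(mu)

    cell_ids = [f"cell_{i}" for i in range(n)]
    gene_ids = [f"gene_{j}" for j in range(cfg.n_genes)]
    cm = CountMatrix(counts, cell_ids, gene_ids)
    cov = CovariateTable(
        pd.DataFrame(
            {
                "line": [f"line{l + 1}" for l in line],
                "protocol": [f"protocol{p + 1}" for p in protocol],
                "library_size": np.log(np.maximum(cm.library_sizes(), 1)),
            },
            index=cell_ids,
        )
    )
    return cm, cov
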