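import numpy as np
import pandas as pd
import pytest

import climoffset as co


@pytest.fixture(scope="session")
def tiny_scenario():
    """Small world for fast unit tests: 6x10 half-degree grid, 60 landraces."""
    return co.SyntheticScenario(
        lat_range=(10.0, 13.0), lon_range=(-5.0, 0.0), n_landraces=60,
        n_adaptive_snps=8, n_neutral_snps=40, n_countries=3, seed=11,
    )


@pytest.fixture(scope="session")
def tiny_world(tiny_scenario):
    """Generated inputs for the tiny scenario, shared across tests."""
    sc = tiny_scenario
    current, future = co.generate_climate(sc)
    cur_metrics = co.compute_metrics(current)
    fut_metrics = co.compute_metrics(future)
    landraces = co.generate_landraces(sc, current)
    lr_metrics = cur_metrics.at_sites(landraces["lat"], landraces["lon"],
                                      ids=landraces.index)
    freqs, truth = co.generate_allele_freqs(sc, landraces, lr_metrics)
    phenos = co.generate_phenotypes(sc, landraces, freqs, truth, metrics=lr_metrics,
                                    grid_metrics=cur_metrics)
    return dict(scenario=sc, current=current, future=future,
                cur_metrics=cur_metrics, fut_metrics=fut_metrics,
                landraces=landraces, lr_metrics=lr_metrics,
                freqs=freqs, truth=truth, phenos=phenos)


@pytest.fixture(scope="session")
def tiny_model(tiny_world):
    """Gradient-forest fit on the tiny world (decorrelated predictors)."""
    w = tiny_world
    kept = co.filter_maf(w["freqs"], 0.10)
    predictors = co.select_uncorrelated(w["lr_metrics"], 0.7)
    model = co.fit(kept, w["lr_metrics"].subset_metrics(predictors),
                   n_trees=60, seed=11)
    return model


def step_model(predictors, edges, cums):
    """Hand-built turnover model for analytic offset/donor tests."""
    return co.TurnoverModel(
        predictors=list(predictors),
        bin_edges={p: np.asarray(e, float) for p, e in zip(predictors, edges)},
        cum_importance={p: np.asarray(c, float) for p, c in zip(predictors, cums)},
        snp_r2=pd.Series(dtype=float),
        importance=pd.Series({p: float(np.asarray(c)[-1]) for p, c in zip(predictors, cums)}),
        n_trees=0,
        seed=0,
    )
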