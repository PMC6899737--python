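"""Stage orchestration: mortality -> functional response -> metabolism
-> energetics, with all intermediate tables written as CSV/JSON."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import io
from .energetics import PreyEnergetics, efficiency_profiles
from .fitting import enumerate_model_zoo, fit_fr_model, fit_mortality, select_by_bic
from .metabolism import fit_metabolic_models, thermal_optimum_celsius

logger = logging.getLogger("thermofr")


def run_fit_mortality(trials: pd.DataFrame, config: dict):
    consts = io.constants_from_config(config)
    controls = trials[~trials["predator_present"]]
    fit = fit_mortality(controls, consts=consts, seed=config["seed"])
    logger.info("mortality selected: %s",
                {ds: c.model for ds, c in fit.selected.items()})
    return fit


def run_fit_fr(trials: pd.DataFrame, mortality, config: dict, zoo_subset: int | None = None):
    """Fit the candidate zoo to the predator-present trials and select by BIC.

    ``zoo_subset`` truncates the zoo (after enumeration order) for quick
    runs; the full 55-model zoo is the default.
    """
    consts = io.constants_from_config(config)
    predators = trials[trials["predator_present"]]
    n_datasets = predators["dataset_id"].nunique()
    zoo = enumerate_model_zoo(n_datasets)
    if zoo_subset is not None:
        zoo = zoo[:zoo_subset]
    fits = []
    for i, spec in enumerate(zoo):
        logger.info("fitting model %d/%d: %s", i + 1, len(zoo), spec.describe())
        fits.append(fit_fr_model(spec, predators, mortality, consts=consts,
                                 n_starts=config["optimizer"]["n_starts"],
                                 seed=config["seed"],
                                 rtol=config["solver"]["rtol"],
                                 atol=config["solver"]["atol"]))
    selection = select_by_bic(fits)
    logger.info("winning model: %s (BIC %.2f)",
                selection.winner.spec.describe(), selection.winner.bic)
    return selection


def run_fit_metabolism(respirometry: pd.DataFrame, config: dict):
    consts = io.constants_from_config(config)
    fits_by_species = {}
    for species, grp in respirometry.groupby("species"):
        fits = fit_metabolic_models(grp, consts=consts)
        fits_by_species[species] = fits
        logger.info("metabolism winner for %s: %s (BIC %.2f)",
                    species, fits[0].describe(), fits[0].bic)
    return fits_by_species


def run_energetics(streams: pd.DataFrame, fr_selection, met_fits, config: dict,
                   field_dataset: str = "field2015"):
    consts = io.constants_from_config(config)
    fr_field = fr_selection.winner.params_for(field_dataset)
    prey = PreyEnergetics(**config["prey"])
    assim = io.assimilation_from_config(config)
    met_winner = met_fits[0] if isinstance(met_fits, list) else met_fits
    eff_cfg = config["energetics"]
    table, smooths = efficiency_profiles(
        streams, fr_field, met_winner,
        predator_mass_mg=eff_cfg["predator_mass_mg"], prey=prey, assim=assim,
        consts=consts, field_rate_multiplier=eff_cfg["field_rate_multiplier"],
        area_scaling=eff_cfg["area_scaling"])
    return table, smooths


def run_pipeline(config: dict, out_dir, trials: pd.DataFrame | None = None,
                 respirometry: pd.DataFrame | None = None,
                 streams: pd.DataFrame | None = None,
                 zoo_subset: int | None = None,
                 field_dataset: str = "field2015") -> Path:
    """Run every stage in order and write artifacts to ``out_dir``.

    Inputs not passed directly are read from the paths in the config;
    a missing required input aborts before any fitting starts.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    paths = config["paths"]
    if trials is None:
        if not paths.get("trials"):
            raise FileNotFoundError("no feeding-trials input supplied")
        trials = io.read_trials(paths["trials"])
    if respirometry is None and paths.get("respirometry"):
        respirometry = io.read_respirometry(paths["respirometry"])
    if streams is None and paths.get("streams"):
        streams = io.read_streams(paths["streams"])
    if streams is not None and respirometry is None:
        raise FileNotFoundError("energetics requested (streams supplied) but no "
                                "respirometry input available")

    io.echo_config(config, out)

    mortality = run_fit_mortality(trials, config)
    io.write_table(mortality.summary_frame(), out / "mortality_fits.csv", config)

    selection = run_fit_fr(trials, mortality, config, zoo_subset=zoo_subset)
    io.write_table(selection.table(), out / "fr_model_ranking.csv", config)
    io.write_table(selection.winner.summary_frame(), out / "fr_winner.csv", config)

    if respirometry is not None:
        met_rows, winners = [], {}
        for species, fits in run_fit_metabolism(respirometry, config).items():
            for f in fits:
                frame = f.summary_frame()
                frame.insert(0, "species", species)
                met_rows.append(frame)
            winners[species] = fits[0]
            topt = (thermal_optimum_celsius(fits[0])
                    if "x2" in fits[0].terms else None)
            if topt is not None:
                logger.info("thermal optimum for %s: %.1f degC", species, topt)
        io.write_table(pd.concat(met_rows, ignore_index=True),
                       out / "metabolic_fits.csv", config)

        if streams is not None:
            species = sorted(winners)[0] if len(winners) == 1 else None
            met = winners[species] if species else list(winners.values())[0]
            table, smooths = run_energetics(streams, selection, met, config,
                                            field_dataset=field_dataset)
            io.write_table(table, out / "efficiency.csv", config)
            io.write_json(smooths, out / "efficiency_smooths.json", config)

    logger.info("pipeline artifacts written to %s", out)
    return out
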