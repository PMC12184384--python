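import pytest

from pvsignal.ingest import (
    MeddraMap,
    clean_reports,
    parse_faers_quarter,
    read_deleted_case_list,
)
from pvsignal.model import normalize_term
from pvsignal.simulate import (
    PlantedSignal,
    SimConfig,
    fixture_small,
    simulate,
    write_fixture_small,
)

TARGET = "IRINOTECAN"


def meddra_from_config(cfg: SimConfig) -> MeddraMap:
    frame = cfg.meddra_map_frame()
    return MeddraMap(
        {normalize_term(pt): soc for pt, soc in zip(frame["pt"], frame["soc"])},
        version="synthetic",
    )


@pytest.fixture(scope="session")
def mini_fixture():
    """The hand-built 20-case dataset as in-memory raw tables."""
    tables, deleted, meddra_df = fixture_small()
    meddra = MeddraMap(
        {normalize_term(pt): soc for pt, soc in zip(meddra_df["pt"], meddra_df["soc"])}
    )
    return tables, set(deleted), meddra


@pytest.fixture(scope="session")
def mini_cleaned(mini_fixture):
    """Target reports, background reports and ledger for the mini-fixture."""
    tables, deleted, meddra = mini_fixture
    return clean_reports(tables, [TARGET], meddra, deleted, "JP")


@pytest.fixture(scope="session")
def mini_files(tmp_path_factory):
    """The mini-fixture written to disk and re-parsed (file round trip)."""
    out = tmp_path_factory.mktemp("fixture_small")
    paths = write_fixture_small(out)
    tables = parse_faers_quarter(
        {k: v for k, v in paths.items() if k in ("demo", "drug", "reac", "ther", "outc", "indi")}
    )
    deleted = read_deleted_case_list([paths["deleted"]])
    meddra = MeddraMap.from_tsv(paths["meddra"])
    return tables, deleted, meddra


@pytest.fixture(scope="session")
def planted_sim():
    """One seeded simulated database with a strong planted signal."""
    cfg = SimConfig(
        n_reports=4000,
        seed=11,
        planted_signals=[PlantedSignal(TARGET, "PT_010", 10.0)],
    )
    return cfg, simulate(cfg)


@pytest.fixture(scope="session")
def planted_cleaned(planted_sim):
    cfg, result = planted_sim
    meddra = meddra_from_config(cfg)
    target, background, ledger = clean_reports(
        result.faers, [TARGET], meddra, set(result.deleted_cases), "JP"
    )
    return target, background, ledger
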