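import logging
from pathlib import Path

import pytest

from screendeconv import RunConfig, SyntheticScreenSpec, generate_screen, run_pipeline

logging.disable(logging.WARNING)


def toy_dir() -> Path:
    from importlib.resources import files
    return Path(str(files("screendeconv") / "data" / "toy"))


@pytest.fixture(scope="session")
def toy() -> Path:
    return toy_dir()


def toy_config(toy: Path, out_dir: Path, **overrides) -> RunConfig:
    kwargs = dict(
        library=str(toy / "library.csv"), hits=str(toy / "hits.txt"),
        id_map=str(toy / "id_map.tsv"), gene_map=str(toy / "gene_map.tsv"),
        out_dir=str(out_dir), drugbank=str(toy / "drugbank.xml"),
        pharmgkb=str(toy / "pharmgkb.tsv"), iuphar=str(toy / "iuphar.json"),
        pubchem=str(toy / "pubchem.csv"), chembl=str(toy / "chembl.csv"),
        gmt=str(toy / "gene_sets.gmt"))
    kwargs.update(overrides)
    return RunConfig(**kwargs)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """One mid-size synthetic campaign shared across the session."""
    spec = SyntheticScreenSpec(n_compounds=150, n_targets=25, seed=42,
                               hit_fraction=0.1, planted_targets=((0, 5.0),))
    return generate_screen(spec, tmp_path_factory.mktemp("bundle"))


@pytest.fixture(scope="session")
def small_bundle_run(small_bundle, tmp_path_factory):
    """The pipeline executed once on the shared bundle."""
    out = tmp_path_factory.mktemp("run")
    cfg = bundle_config(small_bundle, out)
    report = run_pipeline(cfg)
    return small_bundle, out, report


def bundle_config(bundle, out_dir, **overrides) -> RunConfig:
    p = bundle.paths
    kwargs = dict(
        library=str(p["library"]), hits=str(p["hits"]), id_map=str(p["id_map"]),
        gene_map=str(p["gene_map"]), out_dir=str(out_dir),
        drugbank=str(p["drugbank"]), pharmgkb=str(p["pharmgkb"]),
        iuphar=str(p["iuphar"]), pubchem=str(p["pubchem"]),
        chembl=str(p["chembl"]), gmt=str(p["gmt"]))
    kwargs.update(overrides)
    return RunConfig(**kwargs)
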