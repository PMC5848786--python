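import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

from greencam.imstats import process_directory
from greencam.metadata import read_metadata, site_location
from greencam.roi import read_roi_list
from greencam.summary import make_summary
from greencam.synth import SyntheticSiteSpec, make_site_images

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def noiseless_site(tmp_path_factory):
    """A full noiseless synthetic site: daily images for one year.

    Shared across tests; nothing may mutate the directory in place.
    """
    spec = SyntheticSiteSpec(seed=7, noise_sigma=0.0, step=1)
    site_dir, truth = make_site_images(spec, tmp_path_factory.mktemp("site"))
    return spec, site_dir, truth


@pytest.fixture(scope="session")
def noiseless_products(noiseless_site):
    """All-image frame and 3-day summary derived from the noiseless site."""
    spec, site_dir, truth = noiseless_site
    roi = read_roi_list(site_dir / f"{spec.sitename}_DB_0001_roi.csv")
    meta = read_metadata(site_dir / f"{spec.sitename}_meta.json")
    loc = site_location(meta)
    allimage = process_directory(site_dir / "images", roi, loc, mask_dir=site_dir)
    summary = make_summary(allimage, step=3)
    return {
        "spec": spec,
        "site_dir": site_dir,
        "truth": truth,
        "roi": roi,
        "meta": meta,
        "loc": loc,
        "allimage": allimage,
        "summary": summary,
    }


@pytest.fixture()
def jan1():
    return dt.date(2015, 1, 1)
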