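"""Regenerate the packaged standardized actinic-flux tables.

The three presets (high/medium/low) are parameterized by solar zenith
angle and overhead ozone column and produced by the analytic
radiative-transfer surrogate in ``neaspec.photolysis.surrogate_flux``
(Planck photon irradiance at 5772 K, Beer-Lambert ozone Hartley-band +
Rayleigh attenuation, Kasten-Young airmass).  The tables are
non-authoritative placeholders for radiative-transfer model output and
can be replaced by any CSV with the same two-column layout.

Run from the repository root:  python scripts/make_flux_tables.py
"""

from pathlib import Path
import sys

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from neaspec.core_io import write_flux_csv
from neaspec.photolysis import FLUX_PRESETS, surrogate_flux


def main() -> None:
    data_dir = Path(__file__).resolve().parents[1] / "src" / "neaspec" / "data"
    data_dir.mkdir(parents=True, exist_ok=True)
    for label, (zenith, ozone) in FLUX_PRESETS.items():
        flux = surrogate_flux(zenith, ozone)
        comment = (
            "standardized actinic flux preset (analytic surrogate; "
            "non-authoritative, replaceable)\n"
            f"solar zenith angle = {zenith:g} deg, ozone column = {ozone:g} DU, "
            "ground elevation 0 km\n"
            "generated by scripts/make_flux_tables.py"
        )
        out = data_dir / f"flux_{label}.csv"
        write_flux_csv(flux, out, comment)
        print(f"wrote {out} ({len(flux.wavelengths)} rows)")


if __name__ == "__main__":
    main()
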