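"""Bundled example data."""

from importlib import resources

from ..data import read_two_arm

__all__ = ["load_veteran"]


def load_veteran():
    """The Veterans' Administration lung-cancer trial (n=137).

    Two-arm randomized trial in advanced inoperable lung cancer: standard
    therapy (group 1, n=69) versus test chemotherapy (group 2, n=68);
    time is survival in days, 9 observations are censored. The data ship
    with the classic survival-analysis literature and standard survival
    software.

    Returns
    -------
    (reference, test) : tuple of CensoredSample
    """
    path = resources.files(__package__) / "veteran.csv"
    with resources.as_file(path) as p:
        return read_two_arm(p)
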