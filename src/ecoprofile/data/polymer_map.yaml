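# Glycoside-hydrolase family -> polymer substrate map used for the
# polymer-capability profile.  GH18 (chitinases), GH5 (cellulases) and
# GH2 (xylan-active beta-glycosidases) are anchored by the analysis this
# package supports; the remaining assignments follow the common CAZy-based
# polymer scheme and are a curation, editable by the user.
polymers:
  agar:      [GH16, GH50, GH86, GH118]
  cellulose: [GH5, GH6, GH8, GH9, GH44, GH45, GH48]
  chitin:    [GH18, GH19, GH20]
  pectin:    [GH28, GH78, GH88, GH105]
  xylan:     [GH2, GH10, GH11, GH30, GH43, GH67]
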