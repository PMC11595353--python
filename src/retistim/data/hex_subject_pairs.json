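{
  "schema": "retistim.hex-subject-pairs.v1",
  "comment": "Electrode-pair stimulation patterns per subject, RECONSTRUCTED from published figure panels (the source reports them graphically only; treat as editable approximations, not printed data). Electrode indices are row-major over the 5x5 hexagonally packed array: row 0 is the minimum-y row, columns ordered by x within each row.",
  "subjects": {
    "1": {"pairs": [[12, 13]], "note": "single active/ground pair, array centre"},
    "2": {"pairs": [[16, 17], [7, 8]], "note": "two separated pairs giving the higher and lower percepts"},
    "3": {
      "pairs": [
        [0, 1], [1, 2], [2, 3], [3, 4], [4, 3],
        [5, 6], [6, 7], [7, 8], [8, 9], [9, 8],
        [10, 11], [11, 12], [12, 13], [13, 14], [14, 13],
        [15, 16], [16, 17], [17, 18], [18, 19], [19, 18],
        [20, 21], [21, 22], [22, 23], [23, 24], [24, 23]
      ],
      "note": "adjacent-pair sweep: every electrode serves once as the active electrode with an adjacent ground"
    },
    "6": {"pairs": [[11, 12]], "note": "single active/ground pair"}
  }
}
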