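# Helix/loop segmentation of the E. coli YidC TM2-TM6 region (1-based
# E. coli numbering).  Seven predicted helices: five TM helices plus the two
# surface helices of the cytoplasmic helical-paddle hairpin (CH1/CH2).
# Boundaries are the package's estimate, consistent with the per-residue
# region labels of the bundled top-50 pair table.

[[segment]]
name = "TM2"
start = 350
end = 371
kind = "TM"
side = "membrane"
n_side = "periplasmic"

[[segment]]
name = "Loop2-3a"
start = 372
end = 384
kind = "loop"
side = "cytoplasmic"

[[segment]]
name = "CH1"
start = 385
end = 399
kind = "surface_helix"
side = "cytoplasmic"

[[segment]]
name = "CH2"
start = 400
end = 417
kind = "surface_helix"
side = "cytoplasmic"

[[segment]]
name = "Loop2-3b"
start = 418
end = 419
kind = "loop"
side = "cytoplasmic"

[[segment]]
name = "TM3"
start = 420
end = 440
kind = "TM"
side = "membrane"
n_side = "cytoplasmic"

[[segment]]
name = "Loop3-4"
start = 441
end = 462
kind = "loop"
side = "periplasmic"

[[segment]]
name = "TM4"
start = 463
end = 480
kind = "TM"
side = "membrane"
n_side = "periplasmic"

[[segment]]
name = "Loop4-5"
start = 481
end = 494
kind = "loop"
side = "cytoplasmic"

[[segment]]
name = "TM5"
start = 495
end = 508
kind = "TM"
side = "membrane"
n_side = "cytoplasmic"

[[segment]]
name = "Loop5-6"
start = 509
end = 513
kind = "loop"
side = "periplasmic"

[[segment]]
name = "TM6"
start = 514
end = 532
kind = "TM"
side = "membrane"
n_side = "periplasmic"

[[segment]]
name = "c-term"
start = 533
end = 548
kind = "loop"
side = "cytoplasmic"
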