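formula,name,lipid_class,assigned_class
C16H27O7,Tetranor-PGFM,FA,SIL
C20H33O6,PG,FA,NILM
C22H37O6,HEFAD,FA,SIL
C34H67O10NP,GPS,GPL,NILM
C40H78O11NS,(3'-sulfo)GalCer,SPL,NILM
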