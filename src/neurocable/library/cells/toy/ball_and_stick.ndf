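#!ndf
# Toy ball-and-stick cell: a cylindrical soma with standard passive
# membrane parameters and one thin dendritic segment.
CELL /toy
  SEGMENT soma
    PARAMETER CM 0.0164
    PARAMETER DIA 2.0000000000000002e-05
    PARAMETER ELEAK -0.080000000000000002
    PARAMETER LENGTH 4.4699999999999998e-05
    PARAMETER RA 2.5
    PARAMETER RM 1
    PARAMETER Vm_init -0.068000000000000005
    SEGMENT dend
      PARAMETER CM 0.0164
      PARAMETER DIA 2.0000000000000002e-06
      PARAMETER ELEAK -0.080000000000000002
      PARAMETER LENGTH 0.00010000000000000001
      PARAMETER RA 2.5
      PARAMETER RM 1
      PARAMETER Vm_init -0.068000000000000005
    END
  END
END
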