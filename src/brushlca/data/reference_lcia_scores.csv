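programme,scenario,category_id,score
supervised,baseline,CC,1.95E+00
supervised,baseline,EAC,8.11E-03
supervised,baseline,ECF,3.22E+00
supervised,baseline,EUF,5.30E-04
supervised,baseline,EUM,1.93E-03
supervised,baseline,EUT,1.75E-02
supervised,baseline,HCE,1.04E-07
supervised,baseline,HIR,1.41E-01
supervised,baseline,HNC,1.96E-07
supervised,baseline,HOD,3.92E-07
supervised,baseline,HOF,5.97E-03
supervised,baseline,HRI,9.02E-08
supervised,baseline,RDW,2.43E+00
supervised,baseline,RFF,3.19E+01
supervised,baseline,RLU,1.17E+01
supervised,baseline,RMM,1.79E-05
supervised,bamboo_brush,CC,1.66E+00
supervised,bamboo_brush,EAC,7.18E-03
supervised,bamboo_brush,ECF,2.86E+00
supervised,bamboo_brush,EUF,3.80E-04
supervised,bamboo_brush,EUM,1.88E-03
supervised,bamboo_brush,EUT,1.64E-02
supervised,bamboo_brush,HCE,9.53E-08
supervised,bamboo_brush,HIR,1.09E-01
supervised,bamboo_brush,HNC,1.89E-07
supervised,bamboo_brush,HOD,1.27E-07
supervised,bamboo_brush,HOF,5.37E-03
supervised,bamboo_brush,HRI,8.97E-08
supervised,bamboo_brush,RDW,2.32E+00
supervised,bamboo_brush,RFF,2.44E+01
supervised,bamboo_brush,RLU,1.96E+01
supervised,bamboo_brush,RMM,1.38E-05
supervised,double_paste,CC,2.08E+00
supervised,double_paste,EAC,8.75E-03
supervised,double_paste,ECF,3.25E+00
supervised,double_paste,EUF,5.80E-04
supervised,double_paste,EUM,2.17E-03
supervised,double_paste,EUT,1.85E-02
supervised,double_paste,HCE,1.04E-07
supervised,double_paste,HIR,1.40E-01
supervised,double_paste,HNC,2.06E-07
supervised,double_paste,HOD,3.82E-07
supervised,double_paste,HOF,6.32E-03
supervised,double_paste,HRI,1.08E-07
supervised,double_paste,RDW,2.66E+00
supervised,double_paste,RFF,3.50E+01
supervised,double_paste,RLU,1.25E+01
supervised,double_paste,RMM,1.70E-05
provision,baseline,CC,2.89E+00
provision,baseline,EAC,1.36E-02
provision,baseline,ECF,5.28E+00
provision,baseline,EUF,1.06E-03
provision,baseline,EUM,3.70E-03
provision,baseline,EUT,2.80E-02
provision,baseline,HCE,2.59E-07
provision,baseline,HIR,2.40E-01
provision,baseline,HNC,4.51E-07
provision,baseline,HOD,3.33E-07
provision,baseline,HOF,9.24E-03
provision,baseline,HRI,2.28E-07
provision,baseline,RDW,8.37E+00
provision,baseline,RFF,5.19E+01
provision,baseline,RLU,2.08E+01
provision,baseline,RMM,1.87E-05
provision,bamboo_brush,CC,2.72E+00
provision,bamboo_brush,EAC,1.32E-02
provision,bamboo_brush,ECF,5.21E+00
provision,bamboo_brush,EUF,9.60E-04
provision,bamboo_brush,EUM,3.72E-03
provision,bamboo_brush,EUT,2.79E-02
provision,bamboo_brush,HCE,2.56E-07
provision,bamboo_brush,HIR,2.19E-01
provision,bamboo_brush,HNC,4.53E-07
provision,bamboo_brush,HOD,1.34E-07
provision,bamboo_brush,HOF,9.02E-03
provision,bamboo_brush,HRI,2.31E-07
provision,bamboo_brush,RDW,8.29E+00
provision,bamboo_brush,RFF,4.69E+01
provision,bamboo_brush,RLU,2.77E+01
provision,bamboo_brush,RMM,1.65E-05
provision,paper_bag,CC,2.87E+00
provision,paper_bag,EAC,1.36E-02
provision,paper_bag,ECF,5.29E+00
provision,paper_bag,EUF,1.07E-03
provision,paper_bag,EUM,3.71E-03
provision,paper_bag,EUT,2.81E-02
provision,paper_bag,HCE,2.59E-07
provision,paper_bag,HIR,2.40E-01
provision,paper_bag,HNC,4.52E-07
provision,paper_bag,HOD,3.33E-07
provision,paper_bag,HOF,9.24E-03
provision,paper_bag,HRI,2.28E-07
provision,paper_bag,RDW,8.37E+00
provision,paper_bag,RFF,5.16E+01
provision,paper_bag,RLU,2.42E+01
provision,paper_bag,RMM,1.87E-05
provision,bamboo_and_paper,CC,2.71E+00
provision,bamboo_and_paper,EAC,1.31E-02
provision,bamboo_and_paper,ECF,5.21E+00
provision,bamboo_and_paper,EUF,9.60E-04
provision,bamboo_and_paper,EUM,3.73E-03
provision,bamboo_and_paper,EUT,2.80E-02
provision,bamboo_and_paper,HCE,2.56E-07
provision,bamboo_and_paper,HIR,2.20E-01
provision,bamboo_and_paper,HNC,4.53E-07
provision,bamboo_and_paper,HOD,1.35E-07
provision,bamboo_and_paper,HOF,9.02E-03
provision,bamboo_and_paper,HRI,2.31E-07
provision,bamboo_and_paper,RDW,8.28E+00
provision,bamboo_and_paper,RFF,4.65E+01
provision,bamboo_and_paper,RLU,3.12E+01
provision,bamboo_and_paper,RMM,1.64E-05
provision,exclude_water,CC,1.85E+00
provision,exclude_water,EAC,8.33E-03
provision,exclude_water,ECF,2.28E+00
provision,exclude_water,EUF,5.40E-04
provision,exclude_water,EUM,2.50E-03
provision,exclude_water,EUT,1.64E-02
provision,exclude_water,HCE,4.38E-08
provision,exclude_water,HIR,6.19E-02
provision,exclude_water,HNC,1.50E-07
provision,exclude_water,HOD,2.67E-07
provision,exclude_water,HOF,5.61E-03
provision,exclude_water,HRI,1.44E-07
provision,exclude_water,RDW,1.58E+00
provision,exclude_water,RFF,3.57E+01
provision,exclude_water,RLU,1.21E+01
provision,exclude_water,RMM,9.46E-06
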