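state,prevalence_pct,se_pct,published_rank
Alabama,8.0,0.9,35
Alaska,8.8,1.0,29
Arizona,6.9,0.8,43
Arkansas,10.6,1.2,13
California,5.7,0.4,49
Colorado,9.7,1.2,20
Connecticut,7.0,1.0,42
Delaware,9.6,1.2,21
District of Columbia,6.7,1.0,44
Florida,6.0,0.5,48
Georgia,9.1,1.0,26
Hawaii,8.5,1.0,31
Idaho,9.5,1.0,22
Illinois,7.6,0.5,38
Indiana,9.3,1.1,24
Iowa,9.9,0.9,19
Kansas,8.5,1.2,31
Kentucky,12.2,1.2,6
Louisiana,11.7,1.3,8
Maine,9.2,1.1,25
Maryland,6.9,0.9,43
Massachusetts,8.1,1.0,34
Michigan,9.2,0.6,25
Minnesota,8.6,1.0,30
Mississippi,11.1,1.1,10
Missouri,12.2,1.2,6
Montana,13.0,1.3,3
Nebraska,8.4,1.0,32
Nevada,7.7,1.0,37
New Hampshire,10.8,1.1,12
New Jersey,7.8,0.8,37
New Mexico,10.6,1.4,13
New York,6.3,0.5,46
North Carolina,8.3,1.0,33
North Dakota,10.7,1.2,13
Ohio,9.6,0.6,21
Oklahoma,10.7,1.1,13
Oregon,8.5,1.1,31
Pennsylvania,9.7,0.6,20
Rhode Island,7.1,1.1,42
South Carolina,10.5,1.1,14
South Dakota,12.2,1.3,6
Tennessee,9.3,1.0,24
Texas,6.8,0.5,44
Utah,4.5,0.9,51
Vermont,10.9,1.1,11
Virginia,6.9,0.8,43
Washington,9.4,1.3,23
West Virginia,12.6,1.3,4
Wisconsin,10.2,1.2,16
Wyoming,14.3,1.3,1
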